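"""Sample- and marker-level quality control.

The filter chain follows standard SNP-array practice: sample call rate,
then per-marker call rate, minor allele frequency, Hardy–Weinberg exact
test, and window-based LD pruning.  Thresholds use strict "lower than"
comparisons, so a value exactly at a threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, DatasetError, GenotypeDataset

__all__ = [
    "QCReport",
    "filter_samples_by_call_rate",
    "hwe_exact_test",
    "filter_snps",
    "ld_prune",
    "run_qc",
]


@dataclass
class QCReport:
    """Record of removed samples/SNPs and stepwise counts.

    Each removed SNP is attributed to the first criterion that failed it
    in pipeline order (call_rate -> maf -> hwe -> ld).
    """

    samples_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "call_rate"])
    )
    snps_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp_id", "criterion", "value"])
    )
    step_counts: list[tuple[str, int, int]] = field(default_factory=list)
    # (step name, n_samples after, n_snps after)

    def add_step(self, name: str, dataset: GenotypeDataset) -> None:
        self.step_counts.append((name, dataset.n_samples, dataset.n_snps))

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "samples_removed": self.samples_removed,
            "snps_removed": self.snps_removed,
            "steps": pd.DataFrame(
                self.step_counts, columns=["step", "n_samples", "n_snps"]
            ),
        }

    def write_tsv(self, path) -> None:
        frames = self.to_frames()
        with open(path, "w") as fh:
            for name, frame in frames.items():
                fh.write(f"# {name}\n")
                frame.to_csv(fh, sep="\t", index=False)
                fh.write("\n")


def _append_rows(frame: pd.DataFrame, rows: list[tuple]) -> pd.DataFrame:
    if not rows:
        return frame
    new = pd.DataFrame(rows, columns=["snp_id", "criterion", "value"])
    if frame.empty:
        return new
    return pd.concat([frame, new], ignore_index=True)


def filter_samples_by_call_rate(
    dataset: GenotypeDataset, threshold: float = 0.95
) -> tuple[GenotypeDataset, QCReport]:
    """Drop samples with call rate strictly below ``threshold``."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise DatasetError("cannot QC an empty dataset")
    rates = dataset.sample_call_rates()
    keep = rates >= threshold
    report = QCReport(
        samples_removed=pd.DataFrame(
            {
                "sample_id": dataset.samples.loc[~keep, "sample_id"].to_numpy(),
                "call_rate": rates[~keep],
            }
        )
    )
    report.add_step("input", dataset)
    filtered = dataset.subset_samples(np.flatnonzero(keep))
    report.add_step("sample_call_rate", filtered)
    return filtered, report


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def _het_distribution(n: int, n_rare: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given ``n`` diploid genotypes and ``n_rare`` copies of the rarer
    allele, returns the feasible heterozygote counts and their exact
    probabilities under Hardy–Weinberg, via the standard two-term
    recurrence (probabilities are normalized at the end).
    """
    h_min = n_rare % 2
    if n_rare > n:  # rare allele can exceed n only up to 2n - n_rare hom-common
        h_min = max(h_min, 2 * n_rare - 2 * n)
    hs = np.arange(h_min, n_rare + 1, 2)
    probs = np.empty(len(hs))
    probs[0] = 1.0
    for k in range(1, len(hs)):
        h = hs[k - 1]
        n_rr = (n_rare - h) // 2  # rare homozygotes at h
        n_cc = n - h - n_rr  # common homozygotes at h
        # move h -> h+2: one rare hom and one common hom become two hets
        probs[k] = probs[k - 1] * 4.0 * n_rr * n_cc / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    return hs, probs


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided Hardy–Weinberg exact p-value.

    Sums, over all heterozygote counts feasible given the allele counts,
    the probabilities no larger than that of the observed count.
    Monomorphic tables return 1.0 by convention.
    """
    counts = (n_AA, n_Aa, n_aa)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa
    n_rare = min(n_a, 2 * n - n_a)
    if n_rare == 0:
        return 1.0
    hs, probs = _het_distribution(n, n_rare)
    p_obs = probs[np.searchsorted(hs, n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Marker filters
# ---------------------------------------------------------------------------

def filter_snps(
    dataset: GenotypeDataset,
    call_rate: float = 0.95,
    maf: float = 0.05,
    hwe_p: float = 1e-4,
    report: QCReport | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply marker filters in order: call rate, MAF, HWE exact test.

    Call rate and MAF use strict "lower than" comparisons; HWE removes
    markers with exact p strictly below ``hwe_p``.  The HWE test pools
    all samples (no stratification by island), so Wahlund-driven
    exclusions are possible in structured cohorts.
    """
    if dataset.n_samples == 0 or dataset.n_snps == 0:
        raise DatasetError("cannot QC an empty dataset")
    report = report or QCReport()
    if not report.step_counts:
        report.add_step("input", dataset)
    g = dataset.genotypes
    removed: dict[int, tuple[str, float]] = {}

    rates = dataset.snp_call_rates()
    for j in np.flatnonzero(rates < call_rate):
        removed[j] = ("call_rate", rates[j])

    mafs = dataset.minor_allele_frequencies()
    for j in np.flatnonzero(np.nan_to_num(mafs, nan=0.0) < maf):
        if j not in removed:
            removed[j] = ("maf", mafs[j])

    for j in range(dataset.n_snps):
        if j in removed:
            continue
        col = g[:, j]
        n_aa = int((col == 2).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 0).sum())
        p = hwe_exact_test(n_AA, n_het, n_aa)
        if p < hwe_p:
            removed[j] = ("hwe", p)

    order = ["call_rate", "maf", "hwe"]
    rows = [
        (dataset.snps.at[j, "snp_id"], crit, val)
        for j, (crit, val) in sorted(removed.items())
    ]
    report.snps_removed = _append_rows(report.snps_removed, rows)
    keep = np.array([j for j in range(dataset.n_snps) if j not in removed])
    if len(keep) == 0:
        keep = keep.astype(int)
    filtered = dataset.subset_snps(keep)
    for step in order:
        n_after = dataset.n_snps - sum(
            1 for _, (c, _v) in removed.items() if order.index(c) <= order.index(step)
        )
        report.step_counts.append((f"snp_{step}", dataset.n_samples, n_after))
    return filtered, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise squared genotype-count correlation, pairwise-complete.

    ``g`` is (n_samples, w) with MISSING codes; correlations use, for
    each pair of SNPs, the samples called for both.
    """
    x = g.astype(float)
    valid = g != MISSING
    x[~valid] = 0.0
    v = valid.astype(float)
    n = v.T @ v
    sx = x.T @ v
    sxy = x.T @ x
    sxx = (x * x).T @ v
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        var = n * sxx - sx * sx
        denom = var * var.T
        r2 = np.where(denom > 0, cov * cov / denom, 0.0)
    np.fill_diagonal(r2, 0.0)
    r2[n < 2] = 0.0
    return r2


def ld_prune(
    dataset: GenotypeDataset,
    window_snps: int = 50,
    step_snps: int = 5,
    r2_max: float = 0.50,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window LD pruning on genotype-count r².

    Windows of ``window_snps`` SNPs advance by ``step_snps`` within each
    chromosome; while any within-window pair exceeds ``r2_max``, the
    member with the lower MAF is removed (tie: the later by position).
    Removals are permanent across windows.  Returns (kept, removed)
    integer index arrays into the dataset's SNP table.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    if not dataset.is_position_sorted():
        raise DatasetError("dataset must be sorted by chromosome and position")
    mafs = dataset.minor_allele_frequencies()
    removed_mask = np.zeros(dataset.n_snps, dtype=bool)
    chrom = dataset.snps["chrom"].to_numpy()
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            window = idx[start : start + window_snps]
            active = window[~removed_mask[window]]
            if len(active) >= 2:
                r2 = _pairwise_r2(dataset.genotypes[:, active])
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    a, b = active[i], active[j]
                    # drop the lower-MAF member; tie -> later position
                    if mafs[a] < mafs[b] or (mafs[a] == mafs[b] and a > b):
                        drop_local = i
                    else:
                        drop_local = j
                    removed_mask[active[drop_local]] = True
                    r2[drop_local, :] = 0.0
                    r2[:, drop_local] = 0.0
            if start + window_snps >= len(idx):
                break
            start += step_snps
    kept = np.flatnonzero(~removed_mask)
    removed = np.flatnonzero(removed_mask)
    return kept, removed


def run_qc(
    dataset: GenotypeDataset,
    sample_call_rate: float = 0.95,
    snp_call_rate: float = 0.95,
    maf: float = 0.05,
    hwe_p: float = 1e-4,
    ld_window: int = 50,
    ld_step: int = 5,
    ld_r2: float = 0.50,
) -> tuple[GenotypeDataset, QCReport]:
    """Full QC chain: sample call rate, marker filters, LD pruning."""
    ds, report = filter_samples_by_call_rate(dataset, sample_call_rate)
    ds, report = filter_snps(ds, snp_call_rate, maf, hwe_p, report)
    kept, removed = ld_prune(ds, ld_window, ld_step, ld_r2)
    rows = [(ds.snps.at[int(j), "snp_id"], "ld", np.nan) for j in removed]
    report.snps_removed = _append_rows(report.snps_removed, rows)
    ds = ds.subset_snps(kept)
    report.add_step("snp_ld", ds)
    return ds, report
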