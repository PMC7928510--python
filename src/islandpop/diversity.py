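"""Heterozygosity, inbreeding coefficients and runs of homozygosity.

Observed heterozygosity H_O is the per-locus heterozygote fraction among
non-missing calls within a group; expected heterozygosity H_E is
2p(1-p) from the within-group allele frequency (an optional small-sample
2n/(2n-1) correction is available but off by default for the diversity
tables; it is always applied inside the f_is expected-homozygosity sum,
matching the two source conventions).

ROH are detected with the consecutive-runs method: maximal runs of SNPs
per sample and chromosome subject to marker-count, length, heterozygote,
missing-call and inter-marker-gap constraints.  The genomic inbreeding
coefficient f_ROH divides total ROH length by the marker-covered
autosome length (2,610 Mb by default), overall and in length classes
[1,5), [5,20) and [20,inf) Mb.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.stats

from .dataset import MISSING, DatasetError, GenotypeDataset

__all__ = [
    "heterozygosity_stats",
    "brown_forsythe_test",
    "BrownForsytheResult",
    "fis_per_sample",
    "detect_roh",
    "froh",
    "DEFAULT_GENOME_LENGTH_BP",
    "ROH_CLASSES_MB",
]

DEFAULT_GENOME_LENGTH_BP: int = 2_610_000_000

#: f_ROH length classes in Mb: [low, high) with None = open above.
ROH_CLASSES_MB: dict[str, tuple[float, float | None]] = {
    "1_5": (1.0, 5.0),
    "5_20": (5.0, 20.0),
    "gt20": (20.0, None),
}


def _group_locus_stats(
    g: np.ndarray, correction: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (H_O, H_E) within one group of samples."""
    valid = g != MISSING
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(valid, g == 1, False).sum(axis=0) / n
        p = np.where(valid, g, 0).sum(axis=0) / (2.0 * n)
        he = 2.0 * p * (1.0 - p)
        if correction:
            he = he * (2.0 * n) / (2.0 * n - 1.0)
    het[n == 0] = np.nan
    he[n == 0] = np.nan
    return het, he


def heterozygosity_stats(
    dataset: GenotypeDataset,
    grouping: Iterable,
    he_correction: bool = False,
) -> pd.DataFrame:
    """Mean/SD/min/max of per-locus H_O and H_E per group.

    ``grouping`` assigns each sample to one group label.  Loci with no
    called genotype in a group are excluded from that group's summary.
    """
    labels = np.asarray(list(grouping))
    if len(labels) != dataset.n_samples:
        raise DatasetError("grouping length != sample count")
    rows = []
    for grp in pd.unique(labels):
        members = np.flatnonzero(labels == grp)
        if len(members) == 0:
            raise DatasetError(f"group {grp!r} has no samples")
        ho, he = _group_locus_stats(dataset.genotypes[members], he_correction)
        for name, vals in (("H_O", ho), ("H_E", he)):
            v = vals[~np.isnan(vals)]
            sd = v.std(ddof=1) if len(v) > 1 else np.nan
            rows.append((grp, name, v.mean(), sd, v.min(), v.max(), len(v)))
    return pd.DataFrame(
        rows, columns=["group", "statistic", "mean", "sd", "min", "max", "n_loci"]
    )


@dataclass
class BrownForsytheResult:
    statistic: float
    df_between: int
    df_within: int
    p_value: float


def brown_forsythe_test(values, group_labels) -> BrownForsytheResult:
    """Brown–Forsythe homogeneity-of-variance test.

    One-way ANOVA F on absolute deviations from the group medians.
    Groups whose deviations are all zero are permitted; if every
    deviation in every group is zero the statistic is 0 with p = 1.
    """
    x = np.asarray(values, dtype=float)
    labels = np.asarray(list(group_labels))
    if len(x) != len(labels):
        raise ValueError("values and group_labels must have equal length")
    groups = [x[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 values each")
    z = [np.abs(g - np.median(g)) for g in groups]
    k = len(z)
    n_total = sum(len(g) for g in z)
    grand = np.concatenate(z).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in z)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in z)
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        stat = 0.0 if ss_between == 0.0 else np.inf
    else:
        stat = (ss_between / df_b) / (ss_within / df_w)
    p = 1.0 if stat == 0.0 else float(scipy.stats.f.sf(stat, df_b, df_w))
    return BrownForsytheResult(float(stat), df_b, df_w, p)


def fis_per_sample(dataset: GenotypeDataset) -> pd.DataFrame:
    """Method-of-moments inbreeding coefficient per sample.

    F = (O_hom - E_hom) / (L - E_hom) with the expected homozygosity
    per locus 1 - 2p(1-p)·2n/(2n-1), allele frequency p and genotyped
    count n taken from the full cohort, summed over the loci called in
    the sample.  Negative values denote heterozygote excess, positive
    values heterozygote deficit.  Degenerate samples (L = E_hom) get NaN.
    """
    g = dataset.genotypes
    valid = g != MISSING
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, g, 0).sum(axis=0) / (2.0 * n)
        e_hom = 1.0 - 2.0 * p * (1.0 - p) * (2.0 * n) / (2.0 * n - 1.0)
    usable = (n >= 1) & np.isfinite(e_hom)
    obs_hom = (valid & (g != 1) & usable[None, :]).sum(axis=1).astype(float)
    l_called = (valid & usable[None, :]).sum(axis=1).astype(float)
    e_sum = (valid * np.where(usable, e_hom, 0.0)[None, :]).sum(axis=1)
    denom = l_called - e_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(np.abs(denom) > 1e-12, (obs_hom - e_sum) / denom, np.nan)
    return pd.DataFrame(
        {
            "sample_id": dataset.samples["sample_id"],
            "n_loci": l_called.astype(int),
            "obs_hom": obs_hom.astype(int),
            "exp_hom": e_sum,
            "fis": f,
        }
    )


# ---------------------------------------------------------------------------
# Runs of homozygosity
# ---------------------------------------------------------------------------

def _blocks_by_gap(pos: np.ndarray, max_gap: float) -> list[tuple[int, int]]:
    """Split [0, len) into maximal index blocks with no gap > max_gap."""
    if len(pos) == 0:
        return []
    breaks = np.flatnonzero(np.diff(pos) > max_gap)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks + 1, [len(pos)]])
    return list(zip(starts, ends))


def _scan_runs(
    codes: np.ndarray,
    pos: np.ndarray,
    max_het: int,
    max_missing: int,
) -> list[tuple[int, int]]:
    """Maximal candidate runs in one gap-free block.

    ``codes`` is 0 = homozygous, 1 = heterozygous, 2 = missing.  A run
    must start and end on a homozygous call and contain at most
    ``max_het`` heterozygous and ``max_missing`` missing calls.  Returns
    (start, end) inclusive index pairs of runs not contained in any
    other valid run (two-pointer sweep: the right frontier is monotone).
    """
    hom_idx = np.flatnonzero(codes == 0)
    if len(hom_idx) == 0:
        return []
    # prefix counts: H[k] = heterozygous calls in codes[:k], M[k] missing
    h_pre = np.concatenate([[0], np.cumsum(codes == 1)])
    m_pre = np.concatenate([[0], np.cumsum(codes == 2)])
    # furthest admissible end for each start i: largest j with
    # H[j+1] <= H[i] + max_het and M[j+1] <= M[i] + max_missing
    t_h = np.searchsorted(h_pre, h_pre[hom_idx] + max_het, side="right") - 1
    t_m = np.searchsorted(m_pre, m_pre[hom_idx] + max_missing, side="right") - 1
    j_max = np.minimum(t_h, t_m) - 1
    # retreat each end to the last homozygous call at or before it
    end_slot = np.searchsorted(hom_idx, j_max, side="right") - 1
    runs: list[tuple[int, int]] = []
    prev_end = -1
    for i, slot in zip(hom_idx, end_slot):
        if slot < 0:
            continue
        j = int(hom_idx[slot])
        if j >= i and j > prev_end:  # drop runs contained in an earlier one
            runs.append((int(i), j))
            prev_end = j
    return runs


def detect_roh(
    dataset: GenotypeDataset,
    min_snps: int = 25,
    min_length_bp: float = 1_000_000,
    max_het: int = 1,
    max_missing: int = 1,
    max_gap_bp: float = 1_000_000,
) -> pd.DataFrame:
    """Detect runs of homozygosity with the consecutive-runs method.

    Per sample and chromosome, candidate runs are maximal stretches of
    consecutive SNPs that (i) start and end on homozygous calls,
    (ii) contain at most ``max_het`` heterozygous and ``max_missing``
    missing calls and (iii) have no inter-marker gap above
    ``max_gap_bp``.  Candidates failing ``min_snps`` or ``min_length_bp``
    (length = end_bp - start_bp) are dropped; remaining candidates that
    overlap (two maximal runs can share a heterozygote's flanks) are
    resolved greedily left to right, so reported segments never overlap.
    """
    if not dataset.is_position_sorted():
        raise DatasetError("dataset must be sorted by chromosome and position")
    chrom = dataset.snps["chrom"].to_numpy()
    pos_all = dataset.snps["pos_bp"].to_numpy()
    rows = []
    for c in pd.unique(chrom):
        sel = np.flatnonzero(chrom == c)
        pos = pos_all[sel]
        g_chr = dataset.genotypes[:, sel]
        blocks = _blocks_by_gap(pos, max_gap_bp)
        for i_samp in range(dataset.n_samples):
            g = g_chr[i_samp]
            codes = np.where(g == MISSING, 2, np.where(g == 1, 1, 0)).astype(np.int8)
            for b0, b1 in blocks:
                last_end = -1  # greedy left-to-right overlap resolution
                for s, e in _scan_runs(codes[b0:b1], pos[b0:b1], max_het, max_missing):
                    start_bp = int(pos[b0 + s])
                    end_bp = int(pos[b0 + e])
                    n_run = e - s + 1
                    if n_run < min_snps or end_bp - start_bp < min_length_bp:
                        continue
                    if s <= last_end:
                        continue
                    last_end = e
                    rows.append(
                        (
                            dataset.samples.at[i_samp, "sample_id"],
                            c,
                            start_bp,
                            end_bp,
                            n_run,
                            end_bp - start_bp,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"],
    )


def froh(
    segments: pd.DataFrame,
    sample_ids: Iterable,
    genome_length_bp: float = DEFAULT_GENOME_LENGTH_BP,
    classes: dict[str, tuple[float, float | None]] = ROH_CLASSES_MB,
) -> pd.DataFrame:
    """Genomic inbreeding coefficients from ROH, overall and per class.

    f_ROH = sum of segment lengths / genome_length_bp; class boundaries
    are [low, high) in Mb.  Overlapping segments within one sample raise
    a validation error.
    """
    seg = segments.copy()
    for sid, chrom_grp in seg.groupby(["sample_id", "chrom"]):
        s = chrom_grp.sort_values("start_bp")
        if (s["start_bp"].to_numpy()[1:] < s["end_bp"].to_numpy()[:-1]).any():
            raise DatasetError(f"overlapping ROH segments for sample {sid[0]!r}")
    rows = []
    by_sample = dict(tuple(seg.groupby("sample_id"))) if len(seg) else {}
    for sid in sample_ids:
        s = by_sample.get(sid)
        lengths = s["length_bp"].to_numpy(dtype=float) if s is not None else np.array([])
        record = {"sample_id": sid, "froh_all": lengths.sum() / genome_length_bp}
        for name, (lo, hi) in classes.items():
            lo_bp = lo * 1e6
            hi_bp = np.inf if hi is None else hi * 1e6
            in_class = lengths[(lengths >= lo_bp) & (lengths < hi_bp)]
            record[f"froh_{name}"] = in_class.sum() / genome_length_bp
        rows.append(record)
    return pd.DataFrame(rows)
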