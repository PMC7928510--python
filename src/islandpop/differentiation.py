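"""Genetic differentiation: Weir–Cockerham F_ST and Nei (1972) distances.

The F_ST estimator uses the two-population variance components
a (among populations), b (among individuals within populations) and
c (within individuals), accommodating unequal sample sizes and observed
heterozygosity.  The multilocus estimate is the ratio of sums
sum(a) / sum(a+b+c) over loci with a defined denominator — not the mean
of per-locus ratios.  Bootstrap confidence intervals resample loci with
replacement and take percentile quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .dataset import MISSING, DatasetError, GenotypeDataset

__all__ = [
    "wc_fst_components",
    "wc_fst",
    "pairwise_fst_bootstrap",
    "FstResult",
    "nei_distance_matrix",
    "SMALL_GROUP_WARN",
]

SMALL_GROUP_WARN = 10


def _group_counts(g: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus genotyped count n, allele-A frequency p, observed het h."""
    valid = g != MISSING
    n = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(valid, g, 0).sum(axis=0) / (2.0 * n)
        h = np.where(valid, g == 1, False).sum(axis=0) / n
    return n, p, h


def wc_fst_components(
    n1, p1, h1, n2, p2, h2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham variance components (a, b, c) for two populations.

    Inputs are per-locus genotyped sample counts, allele frequencies and
    observed heterozygote fractions.  Loci where either population has
    fewer than two genotyped samples yield NaN components.
    """
    n1, p1, h1, n2, p2, h2 = map(np.asarray, (n1, p1, h1, n2, p2, h2))
    r = 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        pq = p_bar * (1.0 - p_bar)
        a = (n_bar / n_c) * (
            s2 - (pq - (r - 1.0) / r * s2 - h_bar / 4.0) / (n_bar - 1.0)
        )
        b = (n_bar / (n_bar - 1.0)) * (
            pq - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar
        )
        c = h_bar / 2.0
    bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(p1) | ~np.isfinite(p2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def _components_for_groups(
    dataset: GenotypeDataset, mask_a: np.ndarray, mask_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    ga = dataset.genotypes[mask_a]
    gb = dataset.genotypes[mask_b]
    a, b, c = wc_fst_components(*_group_counts(ga), *_group_counts(gb))
    denom = a + b + c
    # monomorphic-across-both loci have zero denominator: excluded
    denom = np.where(np.abs(denom) < 1e-300, np.nan, denom)
    return a, denom


def wc_fst(
    dataset: GenotypeDataset, grouping, group_a, group_b
) -> tuple[np.ndarray, float]:
    """Per-locus and multilocus Weir–Cockerham theta for two groups.

    Returns (per-locus theta with NaN at excluded loci, multilocus
    ratio-of-sums theta).
    """
    labels = np.asarray(list(grouping))
    mask_a = labels == group_a
    mask_b = labels == group_b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise DatasetError("each group needs >=2 samples")
    for name, m in ((group_a, mask_a), (group_b, mask_b)):
        if m.sum() < SMALL_GROUP_WARN:
            warnings.warn(
                f"group {name!r} has only {int(m.sum())} samples; "
                "distance/F_ST estimates inflate with small samples",
                stacklevel=2,
            )
    a, denom = _components_for_groups(dataset, mask_a, mask_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta_locus = a / denom
    ok = np.isfinite(denom) & np.isfinite(a)
    if not ok.any():
        raise DatasetError("no informative loci for this group pair")
    theta = float(a[ok].sum() / denom[ok].sum())
    return theta_locus, theta


@dataclass
class FstResult:
    """Multilocus theta with a locus-bootstrap percentile CI."""

    group_a: str
    group_b: str
    theta: float
    ci_lower: float
    ci_upper: float
    n_boot: int
    n_loci: int
    theta_locus: np.ndarray


def _bootstrap_theta(
    a: np.ndarray, denom: np.ndarray, n_boot: int, ci: float, rng
) -> tuple[float, float]:
    ok = np.isfinite(denom) & np.isfinite(a)
    a, denom = a[ok], denom[ok]
    L = len(a)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, L, size=L)
        reps[b] = a[idx].sum() / denom[idx].sum()
    alpha = (1.0 - ci) / 2.0
    return float(np.quantile(reps, alpha)), float(np.quantile(reps, 1.0 - alpha))


def pairwise_fst_bootstrap(
    dataset: GenotypeDataset,
    grouping,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
) -> list[FstResult]:
    """Weir–Cockerham theta with bootstrap CI for every group pair.

    Loci are resampled with replacement independently per pair; results
    are deterministic under ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    labels = np.asarray(list(grouping))
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise DatasetError("need >=2 groups")
    root = np.random.default_rng(seed)
    results = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            rng = np.random.default_rng(root.integers(2**31))
            theta_locus, theta = wc_fst(dataset, labels, groups[i], groups[j])
            mask_a = labels == groups[i]
            mask_b = labels == groups[j]
            a, denom = _components_for_groups(dataset, mask_a, mask_b)
            lo, hi = _bootstrap_theta(a, denom, n_boot, ci, rng)
            ok = np.isfinite(denom) & np.isfinite(a)
            results.append(
                FstResult(
                    str(groups[i]), str(groups[j]), theta, lo, hi,
                    n_boot, int(ok.sum()), theta_locus,
                )
            )
    return results


def nei_distance_matrix(dataset: GenotypeDataset, grouping) -> tuple[list, np.ndarray]:
    """Nei (1972) standard genetic distance between all group pairs.

    D = -ln(J_xy / sqrt(J_x J_y)) with gene identities averaged over
    the loci where both groups have called genotypes.
    """
    labels = np.asarray(list(grouping))
    groups = list(pd.unique(labels))
    freqs = {}
    for g in groups:
        _, p, _ = _group_counts(dataset.genotypes[labels == g])
        freqs[g] = p
    n = len(groups)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            px, py = freqs[groups[i]], freqs[groups[j]]
            ok = np.isfinite(px) & np.isfinite(py)
            if not ok.any():
                raise DatasetError("no shared informative loci for a group pair")
            qx, qy = 1 - px[ok], 1 - py[ok]
            jx = (px[ok] ** 2 + qx**2).mean()
            jy = (py[ok] ** 2 + qy**2).mean()
            jxy = (px[ok] * py[ok] + qx * qy).mean()
            if jx <= 0 or jy <= 0 or jxy <= 0:
                raise DatasetError("degenerate gene identities for a group pair")
            d = -np.log(jxy / np.sqrt(jx * jy))
            dist[i, j] = dist[j, i] = max(d, 0.0)
    return [str(g) for g in groups], dist
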