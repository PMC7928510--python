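"""Pairwise relatedness and genetic-structure detection.

Implements the method-of-moments IBD estimator (pi-hat = P(IBD=2) +
0.5·P(IBD=1)) from IBS counts and cohort allele frequencies, the
variance-standardized genomic relationship matrix (GRM), a Pearson
similarity matrix over GRM rows with k-means clustering, and PCA as the
eigendecomposition of the GRM.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .dataset import MISSING, DatasetError, GenotypeDataset

__all__ = [
    "ibd_moments",
    "pihat_pairs",
    "pihat_matrix",
    "grm",
    "similarity_and_kmeans",
    "pca",
    "PCAResult",
]

MIN_SHARED_LOCI = 100


def _expected_ibs_given_ibd(p: np.ndarray) -> dict[tuple[int, int], np.ndarray]:
    """Per-locus P(IBS=s | IBD=k) under Hardy–Weinberg at frequency p.

    Keys are (ibs, ibd).  Sample-size bias corrections are not applied
    (frequencies are treated as known); a correction toggle lives in
    :func:`ibd_moments`.
    """
    q = 1.0 - p
    return {
        (0, 0): 2 * p**2 * q**2,
        (1, 0): 4 * p**3 * q + 4 * p * q**3,
        (2, 0): p**4 + q**4 + 4 * p**2 * q**2,
        (1, 1): 2 * p**2 * q + 2 * p * q**2,
        (2, 1): p**3 + q**3 + p**2 * q + p * q**2,
        (2, 2): np.ones_like(p),
    }


def ibd_moments(
    g1: np.ndarray,
    g2: np.ndarray,
    freqs: np.ndarray,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Method-of-moments IBD-state estimates for genotype row pairs.

    ``g1``/``g2`` are (n_pairs, L) allele-count arrays (MISSING allowed)
    and ``freqs`` the cohort allele-A frequencies.  Loci with MAF below
    ``maf_min`` or a missing call in either member are excluded per
    pair.  Negative moment estimates are truncated to zero and the
    (P0, P1, P2) triple renormalized.  Returns one row per pair with
    P0, P1, P2, pihat, n_loci and a low-confidence flag (< 100 shared
    loci).
    """
    g1 = np.atleast_2d(g1)
    g2 = np.atleast_2d(g2)
    p = np.asarray(freqs, dtype=float)
    informative = np.minimum(p, 1 - p) >= maf_min
    exp = _expected_ibs_given_ibd(p)

    shared = (g1 != MISSING) & (g2 != MISSING) & informative[None, :]
    ibs = 2 - np.abs(g1.astype(np.int16) - g2.astype(np.int16))
    n0 = ((ibs == 0) & shared).sum(axis=1).astype(float)
    n1 = ((ibs == 1) & shared).sum(axis=1).astype(float)
    n_loci = shared.sum(axis=1).astype(float)
    n2 = n_loci - n0 - n1

    e00 = shared @ exp[(0, 0)]
    e10 = shared @ exp[(1, 0)]
    e20 = shared @ exp[(2, 0)]
    e11 = shared @ exp[(1, 1)]
    e21 = shared @ exp[(2, 1)]

    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = n0 / e00
        p1 = (n1 - p0 * e10) / e11
        p2 = (n2 - p0 * e20 - p1 * e21) / n_loci
    stacked = np.clip(np.stack([p0, p1, p2]), 0.0, None)
    total = stacked.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stacked = np.where(total > 0, stacked / total, np.nan)
    p0, p1, p2 = stacked
    return pd.DataFrame(
        {
            "P0": p0,
            "P1": p1,
            "P2": p2,
            "pihat": p2 + 0.5 * p1,
            "n_loci": n_loci.astype(int),
            "low_confidence": n_loci < MIN_SHARED_LOCI,
        }
    )


def pihat_pairs(
    dataset: GenotypeDataset,
    pairs: list[tuple[int, int]],
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Pi-hat for explicit sample-index pairs, cohort allele frequencies."""
    freqs = dataset.allele_frequencies()
    i1 = np.array([a for a, _ in pairs])
    i2 = np.array([b for _, b in pairs])
    chunk = max(1, int(2e8 // max(dataset.n_snps, 1)))  # cap working memory
    parts = []
    for s in range(0, len(pairs), chunk):
        parts.append(
            ibd_moments(
                dataset.genotypes[i1[s : s + chunk]],
                dataset.genotypes[i2[s : s + chunk]],
                freqs,
                maf_min,
            )
        )
    out = pd.concat(parts, ignore_index=True)
    ids = dataset.samples["sample_id"].to_numpy()
    out.insert(0, "id1", ids[i1])
    out.insert(1, "id2", ids[i2])
    return out


def pihat_matrix(dataset: GenotypeDataset, maf_min: float = 0.05) -> pd.DataFrame:
    """Pi-hat table for all unordered sample pairs."""
    n = dataset.n_samples
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    return pihat_pairs(dataset, pairs, maf_min)


# ---------------------------------------------------------------------------
# Genomic relationship matrix
# ---------------------------------------------------------------------------

@dataclass
class GRMatrix:
    """Genomic relationships with per-pair locus counts."""

    values: np.ndarray  # (n, n)
    n_loci: np.ndarray  # (n, n) ints
    sample_ids: list


def grm(dataset: GenotypeDataset) -> GRMatrix:
    """Variance-standardized genomic relationship matrix.

    A(j,k) = mean over loci non-missing in both samples of
    (x_j - 2p)(x_k - 2p) / (2p(1-p)), frequencies from the full cohort.
    Monomorphic loci are excluded with a warning.
    """
    p = dataset.allele_frequencies()
    poly = np.isfinite(p) & (p > 0.0) & (p < 1.0)
    if (~poly).any():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic/uncalled loci from GRM",
            stacklevel=2,
        )
    g = dataset.genotypes[:, poly].astype(float)
    p = p[poly]
    valid = g != MISSING
    w = np.where(valid, (g - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :], 0.0)
    counts = valid.astype(float) @ valid.T.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (w @ w.T) / counts
    return GRMatrix(a, counts.astype(int), dataset.samples["sample_id"].tolist())


# ---------------------------------------------------------------------------
# Similarity clustering and PCA
# ---------------------------------------------------------------------------

def similarity_and_kmeans(
    grmatrix: GRMatrix,
    k_range=range(2, 9),
    seed: int = 17,
    n_init: int = 10,
    features: str = "similarity",
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Pearson similarity of GRM rows plus k-means labels for each k.

    ``features`` selects the k-means input: rows of the similarity
    matrix (default, mirroring clustering of the heatmap) or rows of the
    GRM itself (``"grm"``).
    """
    a = grmatrix.values
    if np.any(a.std(axis=1) == 0):
        raise DatasetError("constant GRM row: similarity undefined")
    sim = np.corrcoef(a)
    x = sim if features == "similarity" else a
    labels = {}
    for k in k_range:
        km = KMeans(n_clusters=int(k), n_init=n_init, random_state=seed)
        labels[int(k)] = km.fit_predict(x)
    return sim, labels


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, K) eigenvectors scaled by sqrt(eigenvalue)
    variance_fraction: np.ndarray  # eigenvalue / trace


def pca(dataset_or_grm, n_components: int = 10) -> PCAResult:
    """PCA of genotypes via eigendecomposition of the GRM.

    Scores are top eigenvectors scaled by the square root of their
    eigenvalues; variance fractions are eigenvalues over the GRM trace.
    """
    if isinstance(dataset_or_grm, GenotypeDataset):
        a = grm(dataset_or_grm).values
    else:
        a = dataset_or_grm.values if isinstance(dataset_or_grm, GRMatrix) else np.asarray(dataset_or_grm)
    n = a.shape[0]
    if n_components > n:
        raise ValueError("n_components exceeds sample count")
    eigval, eigvec = np.linalg.eigh((a + a.T) / 2.0)
    order = np.argsort(eigval)[::-1][:n_components]
    vals = np.clip(eigval[order], 0.0, None)
    vecs = eigvec[:, order]
    # sign convention: largest-magnitude loading positive
    for k in range(vecs.shape[1]):
        i = np.argmax(np.abs(vecs[:, k]))
        if vecs[i, k] < 0:
            vecs[:, k] = -vecs[:, k]
    scores = vecs * np.sqrt(vals)[None, :]
    return PCAResult(scores, vals / np.trace(a))
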