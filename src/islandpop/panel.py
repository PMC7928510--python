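"""Small discriminatory SNP panels with PCA + discriminant assignment.

Panels are the top-F_ST SNPs between the two islands (Weir–Cockerham
per-locus theta, ties broken by genome order).  Panel genotypes are
mean-imputed, standardized and reduced by PCA; samples are then
assigned with a normal-theory discriminant rule (class-specific
covariances by default, i.e. the quadratic rule implied by "unequal
variances"; a pooled-covariance linear rule is switchable) with prior
probabilities proportional to class sizes.  Error rates come from
leave-one-out cross-validation: each sample is classified by a rule fit
on all the others.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .dataset import MISSING, DatasetError, GenotypeDataset
from .differentiation import wc_fst

__all__ = [
    "rank_snps_by_fst",
    "panel_pca",
    "GaussianDiscriminant",
    "discriminant_loocv",
    "weighted_overall_error",
    "grid_evaluate",
    "DEFAULT_PANEL_SIZES",
    "DEFAULT_PC_COUNTS",
]

DEFAULT_PANEL_SIZES = (25, 50, 100, 150)
DEFAULT_PC_COUNTS = (1, 2, 5, 10)


def rank_snps_by_fst(dataset: GenotypeDataset, island_labels) -> pd.DataFrame:
    """Rank SNPs by per-locus Weir–Cockerham theta between two islands.

    Returns a DataFrame (snp_index, snp_id, theta) sorted by descending
    theta; ties and NaN thetas (monomorphic loci, ranked last) keep
    genome order.
    """
    labels = np.asarray(list(island_labels))
    islands = pd.unique(labels)
    if len(islands) != 2:
        raise DatasetError("need exactly two island labels")
    theta_locus, _ = wc_fst(dataset, labels, islands[0], islands[1])
    order = np.argsort(-np.nan_to_num(theta_locus, nan=-np.inf), kind="stable")
    return pd.DataFrame(
        {
            "snp_index": order,
            "snp_id": dataset.snps["snp_id"].to_numpy()[order],
            "theta": theta_locus[order],
        }
    )


def panel_pca(
    dataset: GenotypeDataset,
    snp_subset,
    n_pcs: int,
    standardize: bool = True,
) -> np.ndarray:
    """PCA scores of a SNP panel, mean-imputed and (optionally) scaled.

    Missing genotypes are imputed with the column mean; columns are
    centered and (by default) scaled to unit variance; zero-variance
    columns are dropped with a warning.  Component signs follow the
    largest-magnitude-loading-positive convention.
    """
    idx = np.asarray(snp_subset)
    if n_pcs > len(idx):
        raise ValueError("n_pcs exceeds panel size")
    x = dataset.genotypes[:, idx].astype(float)
    miss = x == MISSING
    if miss.any():
        col_mean = np.where(miss, np.nan, x).mean(axis=0, where=~miss)
        x[miss] = np.broadcast_to(col_mean, x.shape)[miss]
    x -= x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance panel column(s)",
            stacklevel=2,
        )
        x = x[:, keep]
        sd = sd[keep]
    if n_pcs > x.shape[1]:
        raise ValueError("n_pcs exceeds panel size after dropping columns")
    if standardize:
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    for k in range(scores.shape[1]):
        i = np.argmax(np.abs(vt[k]))
        if vt[k, i] < 0:
            scores[:, k] = -scores[:, k]
    return scores


# ---------------------------------------------------------------------------
# Normal-theory discriminant analysis
# ---------------------------------------------------------------------------

@dataclass
class GaussianDiscriminant:
    """Normal-theory discriminant rule with priors proportional to size.

    ``pooled=False`` (default) fits one covariance per class (quadratic
    rule, the "unequal variances" assumption); ``pooled=True`` fits a
    common within-class covariance (linear rule).  Singular class
    covariances (n_class <= dimension) are ridge-regularized with a
    warning.
    """

    pooled: bool = False
    ridge: float = 1e-8

    def fit(self, x: np.ndarray, y: np.ndarray) -> "GaussianDiscriminant":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y)
        self.classes_ = pd.unique(y)
        n, d = x.shape
        self.means_ = {}
        self.covs_ = {}
        self.priors_ = {}
        pooled_acc = np.zeros((d, d))
        for c in self.classes_:
            xc = x[y == c]
            if len(xc) < 2:
                raise ValueError(f"class {c!r} needs >=2 samples")
            self.means_[c] = xc.mean(axis=0)
            dev = xc - self.means_[c]
            self.covs_[c] = dev.T @ dev / (len(xc) - 1)
            pooled_acc += dev.T @ dev
            self.priors_[c] = len(xc) / n
        pooled_cov = pooled_acc / (n - len(self.classes_))
        if self.pooled:
            for c in self.classes_:
                self.covs_[c] = pooled_cov
        self._prepare()
        return self

    def _prepare(self) -> None:
        self._inv = {}
        self._logdet = {}
        for c, cov in self.covs_.items():
            cov = np.atleast_2d(cov)
            eig = np.linalg.eigvalsh(cov)
            if eig.min() <= max(eig.max(), 1.0) * 1e-10:
                warnings.warn(
                    f"singular covariance for class {c!r}; ridge-regularizing",
                    stacklevel=2,
                )
                cov = cov + max(self.ridge, eig.max() * 1e-6) * np.eye(cov.shape[0])
            _, logdet = np.linalg.slogdet(cov)
            self._inv[c] = np.linalg.inv(cov)
            self._logdet[c] = logdet

    def log_posteriors(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        out = np.empty((x.shape[0], len(self.classes_)))
        for k, c in enumerate(self.classes_):
            dev = x - self.means_[c]
            mahal = np.einsum("ij,jk,ik->i", dev, self._inv[c], dev)
            out[:, k] = (
                np.log(self.priors_[c]) - 0.5 * self._logdet[c] - 0.5 * mahal
            )
        return out

    def predict(self, x: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.log_posteriors(x), axis=1)
        return np.asarray(self.classes_)[idx]


def discriminant_loocv(
    scores: np.ndarray, class_labels, pooled: bool = False
) -> tuple[dict, float]:
    """Leave-one-out misclassification rates of the discriminant rule.

    Each sample is classified by a rule fit on all other samples.
    Returns (per-class error dict, overall error = total misclassified
    over total).
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(class_labels)
    n = len(y)
    wrong = np.zeros(n, dtype=bool)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        clf = GaussianDiscriminant(pooled=pooled).fit(x[mask], y[mask])
        wrong[i] = clf.predict(x[i : i + 1])[0] != y[i]
    per_class = {
        c: float(wrong[y == c].mean()) for c in pd.unique(y)
    }
    return per_class, float(wrong.mean())


def weighted_overall_error(
    per_class_rates, class_sizes, integer_counts: bool = True
) -> float:
    """Overall error from per-class rates and class sizes.

    With ``integer_counts`` (default), per-class rates are converted
    back to integer misclassification counts by rounding rate·n before
    pooling — the convention under which published per-class and overall
    rates are mutually consistent.
    """
    rates = np.asarray(per_class_rates, dtype=float)
    sizes = np.asarray(class_sizes, dtype=float)
    if rates.shape != sizes.shape:
        raise ValueError("rates and sizes must have matching shapes")
    if (rates < 0).any() or (rates > 1).any() or (sizes <= 0).any():
        raise ValueError("rates must lie in [0,1] and sizes be positive")
    if integer_counts:
        return float(np.round(rates * sizes).sum() / sizes.sum())
    return float((rates * sizes).sum() / sizes.sum())


def grid_evaluate(
    dataset: GenotypeDataset,
    island_labels=None,
    panel_sizes=DEFAULT_PANEL_SIZES,
    pc_counts=DEFAULT_PC_COUNTS,
    pooled: bool = False,
    nested: bool = False,
    standardize: bool = True,
) -> pd.DataFrame:
    """Evaluate the (panel size x PC count) assignment grid.

    For each cell: select the top-F_ST panel, reduce to ``n_pcs``
    principal components, and estimate per-class and overall
    leave-one-out misclassification rates.  ``nested=True`` repeats the
    panel selection inside every leave-one-out fold (slower, avoids the
    selection optimism of ranking on the full cohort).  Cells whose
    panel size exceeds the available SNPs are skipped with a warning.
    """
    labels = np.asarray(
        list(island_labels)
        if island_labels is not None
        else dataset.samples["island"]
    )
    classes = list(pd.unique(labels))
    sizes = {c: int((labels == c).sum()) for c in classes}
    ranking = rank_snps_by_fst(dataset, labels)
    rows = []
    for m in panel_sizes:
        if m > dataset.n_snps:
            warnings.warn(f"panel size {m} exceeds SNP count; skipped", stacklevel=2)
            continue
        panel = ranking.head(m)
        idx = panel["snp_index"].to_numpy()
        theta = panel["theta"].to_numpy()
        for n_pcs in pc_counts:
            if n_pcs > m:
                warnings.warn(
                    f"{n_pcs} PCs exceeds panel size {m}; skipped", stacklevel=2
                )
                continue
            if nested:
                wrong = np.zeros(len(labels), dtype=bool)
                for i in range(len(labels)):
                    mask = np.ones(len(labels), dtype=bool)
                    mask[i] = False
                    sub = dataset.subset_samples(np.flatnonzero(mask))
                    rank_i = rank_snps_by_fst(sub, labels[mask])
                    idx_i = rank_i.head(m)["snp_index"].to_numpy()
                    scores_i = panel_pca(dataset, idx_i, n_pcs, standardize)
                    clf = GaussianDiscriminant(pooled=pooled).fit(
                        scores_i[mask], labels[mask]
                    )
                    wrong[i] = clf.predict(scores_i[i : i + 1])[0] != labels[i]
                per_class = {c: float(wrong[labels == c].mean()) for c in classes}
                overall = float(wrong.mean())
            else:
                scores = panel_pca(dataset, idx, n_pcs, standardize)
                per_class, overall = discriminant_loocv(scores, labels, pooled)
            row = {
                "panel_size": m,
                "fst_mean": float(np.nanmean(theta)),
                "fst_sd": float(np.nanstd(theta, ddof=1)),
                "n_pcs": n_pcs,
                "overall_error": overall,
            }
            for c in classes:
                row[f"error_{c}"] = per_class[c]
            rows.append(row)
    out = pd.DataFrame(rows)
    # consistency identity: overall equals the size-weighted class mean
    for _, r in out.iterrows():
        w = weighted_overall_error(
            [r[f"error_{c}"] for c in classes],
            [sizes[c] for c in classes],
            integer_counts=False,
        )
        assert abs(w - r["overall_error"]) < 1e-12
    return out
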