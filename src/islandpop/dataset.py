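"""In-memory genotype dataset shared by all analysis stages.

Genotypes are stored as an ``int8`` samples x SNPs matrix of counts of
allele A (0, 1 or 2), with :data:`MISSING` (-1) marking no-calls.  Sample
metadata carries the two-level grouping used throughout (population
"island" and subpopulation "herd"); SNP metadata carries map information
(chromosome, 1-based bp position, allele codes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Missing-genotype code. Never a valid allele count.
MISSING: int = -1

SAMPLE_COLUMNS = ("sample_id", "island", "herd")
SNP_COLUMNS = ("chrom", "snp_id", "pos_bp", "allele_a", "allele_b")


class DatasetError(ValueError):
    """Raised when a dataset violates its structural invariants."""


@dataclass
class GenotypeDataset:
    """SNP-array genotypes plus sample and marker metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` int8 matrix of allele-A counts; -1 missing.
    samples
        DataFrame with columns ``sample_id``, ``island``, ``herd``.
    snps
        DataFrame with columns ``chrom``, ``snp_id``, ``pos_bp``,
        ``allele_a``, ``allele_b``.  Positions are 1-based base pairs.
    """

    genotypes: np.ndarray
    samples: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DatasetError("genotype matrix must be 2-D")
        self.samples = self.samples.reset_index(drop=True)
        self.snps = self.snps.reset_index(drop=True)
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise DatasetError(f"sample table lacks column {col!r}")
        for col in SNP_COLUMNS:
            if col not in self.snps.columns:
                raise DatasetError(f"snp table lacks column {col!r}")
        if len(self.samples) != self.genotypes.shape[0]:
            raise DatasetError("sample table length != genotype rows")
        if len(self.snps) != self.genotypes.shape[1]:
            raise DatasetError("snp table length != genotype columns")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise DatasetError("genotype codes must be in {-1, 0, 1, 2}")
        same = self.snps["allele_a"].astype(str) == self.snps["allele_b"].astype(str)
        if same.any():
            idx = self.snps.index[same][0]
            raise DatasetError(
                f"SNP {self.snps.at[idx, 'snp_id']!r} has identical allele codes"
            )

    # -- basic shape ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def missing_mask(self) -> np.ndarray:
        """Boolean mask of missing calls, same shape as ``genotypes``."""
        return self.genotypes == MISSING

    # -- summary statistics ---------------------------------------------
    def allele_frequencies(self) -> np.ndarray:
        """Frequency of allele A per SNP among non-missing calls (NaN if none)."""
        g = np.ma.masked_equal(self.genotypes, MISSING)
        with np.errstate(invalid="ignore"):
            freq = g.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(freq, dtype=float)

    def minor_allele_frequencies(self) -> np.ndarray:
        p = self.allele_frequencies()
        return np.minimum(p, 1.0 - p)

    def sample_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def snp_call_rates(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset_samples(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.genotypes[index].copy(),
            self.samples.iloc[index].reset_index(drop=True),
            self.snps.copy(),
        )

    def subset_snps(self, index) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.genotypes[:, index].copy(),
            self.samples.copy(),
            self.snps.iloc[index].reset_index(drop=True),
        )

    def sort_by_position(self) -> "GenotypeDataset":
        """Return a copy sorted by (chromosome, bp position), stable."""
        order = self.snps.sort_values(
            ["chrom", "pos_bp"], kind="stable"
        ).index.to_numpy()
        return self.subset_snps(order)

    def is_position_sorted(self) -> bool:
        by_chrom = self.snps.groupby("chrom", sort=False)["pos_bp"]
        return bool(by_chrom.apply(lambda s: s.is_monotonic_increasing).all())

    def copy(self) -> "GenotypeDataset":
        return GenotypeDataset(
            self.genotypes.copy(), self.samples.copy(), self.snps.copy()
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and self.samples[list(SAMPLE_COLUMNS)].equals(
                other.samples[list(SAMPLE_COLUMNS)]
            )
            and self.snps[list(SNP_COLUMNS)].equals(other.snps[list(SNP_COLUMNS)])
        )


class DistanceMatrixExport:
    """Symmetric distance matrix with group labels, validated on construction."""

    def __init__(self, labels, distances, tol: float = 1e-10):
        self.labels = list(labels)
        self.distances = np.asarray(distances, dtype=float)
        d = self.distances
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise DatasetError("distance matrix must be square")
        if d.shape[0] != len(self.labels):
            raise DatasetError("label count does not match matrix size")
        if d.size and np.abs(d - d.T).max() > tol:
            raise DatasetError("distance matrix is asymmetric beyond tolerance")
        if d.size and np.abs(np.diag(d)).max() > tol:
            raise DatasetError("distance matrix diagonal must be zero")
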