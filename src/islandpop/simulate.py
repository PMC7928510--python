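"""Synthetic genotype cohorts with known truth.

The generator emulates a two-island sheep sampling design: two
populations (default 307 and 117 ewes in 18 and 6 herds) genotyped at
~40,000 autosomal biallelic SNPs spread over 26 chromosomes totalling
2,610 Mb.  Allele frequencies follow a two-level Balding–Nichols
hierarchy (ancestral -> island -> herd), individuals are drawn
binomially from their herd frequencies, a configurable subset is
admixed at the allele-frequency level between the two islands, close
relatives are produced by gene dropping with Haldane recombination at
1 cM/Mb, and autozygosity is injected as forced-homozygous segments.

Every generator takes a :class:`numpy.random.Generator` (or seed) and is
reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset

__all__ = [
    "SimConfig",
    "TruthRecord",
    "FrequencyTables",
    "sample_hierarchical_frequencies",
    "simulate_dataset",
    "simulate_relative_pairs",
    "inject_autozygosity",
    "RELATIONSHIPS",
]


class ParameterError(ValueError):
    """Raised for invalid simulation parameters."""


#: Supported pedigree relationships and their expected pi-hat.
RELATIONSHIPS: dict[str, float] = {
    "duplicate": 1.0,
    "parent-offspring": 0.5,
    "full-sib": 0.5,
    "half-sib": 0.25,
    "first-cousin": 0.125,
    "first-cousin-once-removed": 0.0625,
    "unrelated": 0.0,
}

# Sheep-like relative autosome lengths (26 autosomes), rescaled so the
# simulated genome totals exactly 2,610 Mb.
_REL_CHROM_LENGTHS = np.array(
    [
        275, 249, 224, 119, 108, 117, 100, 91, 95, 86, 62, 79, 83,
        63, 80, 71, 72, 68, 61, 51, 50, 51, 62, 42, 45, 44,
    ],
    dtype=float,
)

_DEFAULT_GENOME_BP = 2_610_000_000

# Default herd sizes: island A = 18 herds (307 animals), island B = 6 herds
# (117 animals), matching the emulated sampling design.
_DEFAULT_HERDS: dict[str, tuple[int, ...]] = {
    "A": (21, 20, 19, 7, 19, 16, 13, 20, 11, 13, 18, 20, 21, 21, 17, 22, 20, 9),
    "B": (19, 19, 19, 19, 21, 20),
}


def default_chromosome_lengths(
    total_bp: int = _DEFAULT_GENOME_BP, n_chromosomes: int = 26
) -> tuple[int, ...]:
    """Autosome lengths in bp, sheep-like proportions, summing to total_bp."""
    rel = _REL_CHROM_LENGTHS[:n_chromosomes]
    lengths = np.floor(rel / rel.sum() * total_bp).astype(np.int64)
    lengths[0] += total_bp - lengths.sum()
    return tuple(int(x) for x in lengths)


@dataclass
class SimConfig:
    """Parameters of the hierarchical cohort generator.

    F_ST-like parameters are Balding–Nichols concentration values:
    ``fst_island`` controls island-vs-ancestral drift, ``fst_herd``
    herd-vs-island drift.  ``admixed_fraction`` of samples receive an
    own-island ancestry proportion q drawn from ``admix_q_range``; the
    rest have q = 1.
    """

    n_snps: int = 40_000
    n_chromosomes: int = 26
    chromosome_lengths_bp: tuple[int, ...] = field(
        default_factory=default_chromosome_lengths
    )
    ancestral_maf_range: tuple[float, float] = (0.05, 0.95)
    fst_island: float = 0.01
    fst_herd: float = 0.05
    herd_sizes: Mapping[str, Sequence[int]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in _DEFAULT_HERDS.items()}
    )
    admixed_fraction: float = 0.25
    admix_q_range: tuple[float, float] = (0.5, 1.0)
    missing_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fst_island < 1 or not 0 < self.fst_herd < 1:
            raise ParameterError("F_ST parameters must lie in (0, 1)")
        if len(self.chromosome_lengths_bp) != self.n_chromosomes:
            raise ParameterError("chromosome_lengths_bp length != n_chromosomes")
        if any(l <= 0 for l in self.chromosome_lengths_bp):
            raise ParameterError("chromosome lengths must be positive")
        if len(self.herd_sizes) != 2:
            raise ParameterError("exactly two islands are supported")
        for isl, sizes in self.herd_sizes.items():
            if any(n <= 0 for n in sizes):
                raise ParameterError(f"herd sizes for island {isl!r} must be > 0")
        lo, hi = self.ancestral_maf_range
        if not 0 < lo < hi < 1:
            raise ParameterError("ancestral_maf_range must satisfy 0 < lo < hi < 1")
        if not 0 <= self.admixed_fraction <= 1:
            raise ParameterError("admixed_fraction must lie in [0, 1]")

    @property
    def islands(self) -> list[str]:
        return list(self.herd_sizes)

    @property
    def n_samples(self) -> int:
        return int(sum(sum(v) for v in self.herd_sizes.values()))

    @property
    def genome_length_bp(self) -> int:
        return int(sum(self.chromosome_lengths_bp))


@dataclass
class TruthRecord:
    """Ground truth accompanying a simulated dataset."""

    samples: pd.DataFrame  # sample_id, island, herd, q
    autozygous_segments: pd.DataFrame  # sample_id, chrom, start_bp, end_bp
    relationships: pd.DataFrame  # sample_id_1, sample_id_2, relationship


@dataclass
class FrequencyTables:
    """Ancestral, per-island and per-herd allele frequencies."""

    ancestral: np.ndarray  # (L,)
    island: dict[str, np.ndarray]  # island -> (L,)
    herd: dict[tuple[str, int], np.ndarray]  # (island, herd index) -> (L,)


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def balding_nichols_frequencies(
    p: np.ndarray, c: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw subpopulation frequencies Beta(p(1-c)/c, (1-p)(1-c)/c).

    The draw has mean p and variance c·p(1-p).  c must lie in (0, 1).
    """
    if not 0 < c < 1:
        raise ParameterError("Balding–Nichols parameter must lie in (0, 1)")
    scale = (1.0 - c) / c
    out = rng.beta(p * scale, (1.0 - p) * scale)
    return np.clip(out, 1e-9, 1.0 - 1e-9)


def sample_hierarchical_frequencies(
    config: SimConfig, rng=None
) -> FrequencyTables:
    """Draw ancestral, island and herd allele frequencies per SNP."""
    rng = _rng(rng if rng is not None else config.seed)
    lo, hi = config.ancestral_maf_range
    ancestral = rng.uniform(lo, hi, size=config.n_snps)
    island = {
        isl: balding_nichols_frequencies(ancestral, config.fst_island, rng)
        for isl in config.islands
    }
    herd = {}
    for isl, sizes in config.herd_sizes.items():
        for h in range(len(sizes)):
            herd[(isl, h)] = balding_nichols_frequencies(
                island[isl], config.fst_herd, rng
            )
    return FrequencyTables(ancestral, island, herd)


def snp_positions(config: SimConfig, rng) -> pd.DataFrame:
    """Uniform sorted SNP positions apportioned to chromosomes by length."""
    rng = _rng(rng)
    lengths = np.asarray(config.chromosome_lengths_bp, dtype=float)
    share = lengths / lengths.sum() * config.n_snps
    counts = np.floor(share).astype(int)
    # largest-remainder apportionment of the leftover SNPs
    rem = share - counts
    for idx in np.argsort(rem)[::-1][: config.n_snps - counts.sum()]:
        counts[idx] += 1
    rows = []
    for c, (n, length) in enumerate(zip(counts, lengths), start=1):
        pos = np.unique(rng.integers(1, int(length) + 1, size=n))
        while len(pos) < n:  # top up after collisions
            extra = rng.integers(1, int(length) + 1, size=n - len(pos))
            pos = np.unique(np.concatenate([pos, extra]))
        for p in pos[:n]:
            rows.append((str(c), int(p)))
    snps = pd.DataFrame(rows, columns=["chrom", "pos_bp"])
    snps.insert(1, "snp_id", [f"snp{i + 1}" for i in range(len(snps))])
    snps["allele_a"] = "A"
    snps["allele_b"] = "B"
    return snps


def simulate_dataset(
    config: SimConfig, rng=None
) -> tuple[GenotypeDataset, TruthRecord]:
    """Simulate a two-island hierarchical cohort with optional admixture.

    Unadmixed individuals draw Binomial(2, herd frequency) genotypes;
    admixed individuals draw from q·p_herd + (1-q)·p_other_island.
    """
    rng = _rng(rng if rng is not None else config.seed)
    freqs = sample_hierarchical_frequencies(config, rng)
    snps = snp_positions(config, rng)

    sample_rows = []
    geno_blocks = []
    islands = config.islands
    for isl, sizes in config.herd_sizes.items():
        other = islands[1] if isl == islands[0] else islands[0]
        for h, n_h in enumerate(sizes):
            herd_label = f"{isl}{h + 1:02d}"
            q = np.ones(n_h)
            admixed = rng.random(n_h) < config.admixed_fraction
            q[admixed] = rng.uniform(*config.admix_q_range, size=admixed.sum())
            p_eff = (
                q[:, None] * freqs.herd[(isl, h)][None, :]
                + (1.0 - q)[:, None] * freqs.island[other][None, :]
            )
            geno_blocks.append(rng.binomial(2, p_eff).astype(np.int8))
            for k in range(n_h):
                sample_rows.append(
                    (f"{herd_label}_{k + 1:03d}", isl, herd_label, q[k])
                )

    genotypes = np.vstack(geno_blocks)
    if config.missing_rate > 0:
        drop = rng.random(genotypes.shape) < config.missing_rate
        genotypes[drop] = MISSING

    truth_samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "island", "herd", "q"]
    )
    samples = truth_samples[["sample_id", "island", "herd"]].copy()
    ds = GenotypeDataset(genotypes, samples, snps)
    truth = TruthRecord(
        samples=truth_samples,
        autozygous_segments=pd.DataFrame(
            columns=["sample_id", "chrom", "start_bp", "end_bp"]
        ),
        relationships=pd.DataFrame(
            columns=["sample_id_1", "sample_id_2", "relationship"]
        ),
    )
    return ds, truth


# ---------------------------------------------------------------------------
# Gene dropping with recombination
# ---------------------------------------------------------------------------

def recombination_fractions(
    positions_bp: np.ndarray, chrom_codes: np.ndarray, cm_per_mb: float = 1.0
) -> np.ndarray:
    """Per-interval transmission switch probabilities, Haldane map.

    Entry i is the probability that locus i derives from the other
    parental haplotype than locus i-1.  Entry 0 and every chromosome
    start are 0.5 (independent segregation).
    """
    pos = np.asarray(positions_bp, dtype=float)
    r = np.empty(len(pos))
    r[0] = 0.5
    d_morgan = np.diff(pos) * cm_per_mb * 1e-8  # bp * (cM/Mb) -> Morgans
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d_morgan))
    new_chrom = np.empty(len(pos), dtype=bool)
    new_chrom[0] = True
    new_chrom[1:] = chrom_codes[1:] != chrom_codes[:-1]
    r[new_chrom] = 0.5
    return r


def _meiosis(haplotypes: np.ndarray, rec: np.ndarray, rng) -> np.ndarray:
    """One gamete from a (2, L) haplotype pair via a Markov crossover walk."""
    switch = rng.random(len(rec)) < rec
    phase = np.logical_xor.accumulate(switch)
    return np.where(phase, haplotypes[1], haplotypes[0])


def _founder(p: np.ndarray, rng) -> np.ndarray:
    return (rng.random((2, len(p))) < p).astype(np.int8)


def simulate_relative_pairs(
    relationship: str,
    n_pairs: int,
    freqs: np.ndarray,
    positions_bp: np.ndarray,
    chrom_codes: np.ndarray,
    rng=None,
    cm_per_mb: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gene-drop genotype pairs with a known pedigree relationship.

    Founder haplotypes are drawn from ``freqs``; descendants are
    produced by meioses with Haldane recombination at ``cm_per_mb``.
    Returns two (n_pairs, L) genotype arrays (allele counts).
    """
    if relationship not in RELATIONSHIPS:
        raise ParameterError(
            f"unsupported relationship {relationship!r}; "
            f"choose from {sorted(RELATIONSHIPS)}"
        )
    rng = _rng(rng)
    p = np.asarray(freqs, dtype=float)
    rec = recombination_fractions(positions_bp, chrom_codes, cm_per_mb)

    g1 = np.empty((n_pairs, len(p)), dtype=np.int8)
    g2 = np.empty((n_pairs, len(p)), dtype=np.int8)

    def child(mother, father):
        return np.stack([_meiosis(mother, rec, rng), _meiosis(father, rec, rng)])

    for i in range(n_pairs):
        if relationship == "duplicate":
            a = _founder(p, rng)
            b = a
        elif relationship == "parent-offspring":
            parent, mate = _founder(p, rng), _founder(p, rng)
            a = parent
            b = child(parent, mate)
        elif relationship == "full-sib":
            mother, father = _founder(p, rng), _founder(p, rng)
            a, b = child(mother, father), child(mother, father)
        elif relationship == "half-sib":
            shared = _founder(p, rng)
            a = child(shared, _founder(p, rng))
            b = child(shared, _founder(p, rng))
        elif relationship == "first-cousin":
            gm, gf = _founder(p, rng), _founder(p, rng)
            sib1, sib2 = child(gm, gf), child(gm, gf)
            a = child(sib1, _founder(p, rng))
            b = child(sib2, _founder(p, rng))
        elif relationship == "first-cousin-once-removed":
            gm, gf = _founder(p, rng), _founder(p, rng)
            sib1, sib2 = child(gm, gf), child(gm, gf)
            cousin1 = child(sib1, _founder(p, rng))
            cousin2 = child(sib2, _founder(p, rng))
            a = cousin1
            b = child(cousin2, _founder(p, rng))
        else:  # unrelated
            a, b = _founder(p, rng), _founder(p, rng)
        g1[i] = a.sum(axis=0)
        g2[i] = b.sum(axis=0)
    return g1, g2


# ---------------------------------------------------------------------------
# Autozygosity injection
# ---------------------------------------------------------------------------

def inject_autozygosity(
    genotypes: np.ndarray,
    snps: pd.DataFrame,
    chromosome_lengths_bp: Sequence[int],
    f_target: float,
    rng=None,
    segment_length_range_bp: tuple[float, float] = (4e6, 20e6),
    min_segment_bp: float = 1.5e6,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Force non-overlapping genome segments homozygous to reach f_target.

    Heterozygous calls inside each chosen segment are resolved by copying
    a randomly chosen haplotype (0 or 2 with probability 1/2); homozygous
    and missing calls are untouched.  Segment lengths are drawn uniformly
    from ``segment_length_range_bp``, the final segment is trimmed so the
    total equals f_target of the genome within placement granularity.

    Returns the modified genotype vector and the true segment table.
    """
    if not 0 <= f_target <= 1:
        raise ParameterError("f_target must lie in [0, 1]")
    if f_target > 0.95:
        raise ParameterError("f_target > 0.95: segment placement infeasible")
    rng = _rng(rng)
    g = np.asarray(genotypes).copy()
    segments: list[tuple[str, int, int]] = []
    lengths = np.asarray(chromosome_lengths_bp, dtype=np.int64)
    chrom_names = [str(c + 1) for c in range(len(lengths))]
    genome = lengths.sum()
    target_bp = f_target * genome
    placed = 0.0
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(len(lengths))}

    attempts = 0
    while placed < target_bp - 1 and attempts < 100_000:
        attempts += 1
        seg_len = rng.uniform(*segment_length_range_bp)
        seg_len = min(seg_len, max(target_bp - placed, min_segment_bp))
        ci = int(rng.choice(len(lengths), p=lengths / genome))
        if seg_len >= lengths[ci]:
            continue
        start = int(rng.integers(1, lengths[ci] - int(seg_len)))
        end = start + int(seg_len)
        if any(start < e and s < end for s, e in occupied[ci]):
            continue
        occupied[ci].append((start, end))
        segments.append((chrom_names[ci], start, end))
        placed += end - start
    if placed < target_bp - 1:
        raise ParameterError("could not place autozygous segments (genome too full)")

    pos = snps["pos_bp"].to_numpy()
    chrom = snps["chrom"].to_numpy()
    for cname, start, end in segments:
        in_seg = (chrom == cname) & (pos >= start) & (pos < end)
        het = in_seg & (g == 1)
        g[het] = 2 * (rng.random(het.sum()) < 0.5).astype(np.int8)
    seg_df = pd.DataFrame(segments, columns=["chrom", "start_bp", "end_bp"])
    seg_df["length_bp"] = seg_df["end_bp"] - seg_df["start_bp"]
    return g, seg_df.sort_values(["chrom", "start_bp"]).reset_index(drop=True)
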