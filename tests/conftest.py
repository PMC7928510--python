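import numpy as np
import pandas as pd
import pytest

from islandpop.dataset import GenotypeDataset


def make_dataset(
    genotypes,
    islands=None,
    herds=None,
    chrom=None,
    pos=None,
    allele_a=None,
    allele_b=None,
):
    """Assemble a GenotypeDataset from plain arrays with sensible defaults."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "island": islands if islands is not None else ["A"] * n,
            "herd": herds if herds is not None else ["h1"] * n,
        }
    )
    snps = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "snp_id": [f"snp{j}" for j in range(m)],
            "pos_bp": pos if pos is not None else (np.arange(m) + 1) * 1000,
            "allele_a": allele_a if allele_a is not None else ["A"] * m,
            "allele_b": allele_b if allele_b is not None else ["G"] * m,
        }
    )
    return GenotypeDataset(g, samples, snps)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def two_island_dataset():
    """Well-differentiated two-island cohort for structure tests."""
    from islandpop.simulate import SimConfig, simulate_dataset

    cfg = SimConfig(
        n_snps=2000,
        herd_sizes={"A": (25, 25), "B": (25, 25)},
        fst_island=0.20,
        fst_herd=0.01,
        admixed_fraction=0.0,
        seed=11,
    )
    ds, truth = simulate_dataset(cfg)
    return ds, truth
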