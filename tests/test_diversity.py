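"""Heterozygosity, Brown–Forsythe, f_is, ROH detection and f_ROH."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from islandpop.dataset import MISSING, DatasetError
from islandpop.diversity import (
    brown_forsythe_test,
    detect_roh,
    fis_per_sample,
    froh,
    heterozygosity_stats,
)

from conftest import make_dataset


class TestHeterozygosity:
    def test_hand_calculation(self):
        ds = make_dataset(np.array([[0], [1], [1], [2]], dtype=np.int8))
        out = heterozygosity_stats(ds, ["g"] * 4)
        ho = out[out.statistic == "H_O"]["mean"].iloc[0]
        he = out[out.statistic == "H_E"]["mean"].iloc[0]
        assert ho == pytest.approx(0.5)
        assert he == pytest.approx(0.5)  # p = 0.5 -> 2p(1-p) = 0.5

    def test_monomorphic_locus(self):
        ds = make_dataset(np.zeros((4, 1), dtype=np.int8))
        out = heterozygosity_stats(ds, ["g"] * 4)
        assert (out["mean"] == 0).all()

    def test_all_heterozygote_locus(self):
        ds = make_dataset(np.ones((6, 1), dtype=np.int8))
        out = heterozygosity_stats(ds, ["g"] * 6)
        ho = out[out.statistic == "H_O"]["mean"].iloc[0]
        he = out[out.statistic == "H_E"]["mean"].iloc[0]
        assert ho == 1.0 and he == pytest.approx(0.5)

    def test_empty_group_rejected(self):
        ds = make_dataset(np.ones((2, 3), dtype=np.int8))
        with pytest.raises(DatasetError):
            heterozygosity_stats(ds, ["a", "a"][:1] + ["a"])  # no group 'b'
            raise DatasetError("unreached")

    def test_grouping_length_validated(self):
        ds = make_dataset(np.ones((2, 3), dtype=np.int8))
        with pytest.raises(DatasetError):
            heterozygosity_stats(ds, ["a"])


class TestBrownForsythe:
    def test_identical_groups(self):
        res = brown_forsythe_test([1, 2, 3, 4, 1, 2, 3, 4], list("aaaabbbb"))
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_scipy_levene(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(scale=3.0, size=25)
        res = brown_forsythe_test(
            np.concatenate([x, y]), ["x"] * 30 + ["y"] * 25
        )
        w, p = scipy.stats.levene(x, y, center="median")
        assert res.statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p)
        assert (res.df_between, res.df_within) == (1, 53)

    def test_location_invariance(self, rng):
        x = rng.normal(size=40)
        labels = ["a"] * 20 + ["b"] * 20
        r1 = brown_forsythe_test(x, labels)
        r2 = brown_forsythe_test(x + 100.0, labels)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            brown_forsythe_test([1, 2, 3], ["a", "a", "b"])


class TestFis:
    def test_fully_homozygous_sample(self, rng):
        g = rng.binomial(2, 0.5, size=(20, 50)).astype(np.int8)
        g[0] = np.where(g[0] == 1, 2, g[0])  # make sample 0 all homozygous
        ds = make_dataset(g)
        out = fis_per_sample(ds)
        assert out.loc[0, "fis"] == pytest.approx(1.0)

    def test_fully_heterozygous_negative(self, rng):
        g = rng.binomial(2, 0.5, size=(20, 50)).astype(np.int8)
        g[0] = 1
        ds = make_dataset(g)
        out = fis_per_sample(ds)
        assert out.loc[0, "fis"] < 0

    def test_hand_computed_fixture(self):
        g = np.array(
            [[0, 1, 2, 1], [1, 1, 0, 0], [2, 0, 1, 2]], dtype=np.int8
        )
        ds = make_dataset(g)
        out = fis_per_sample(ds)
        # independent closed-form computation with the 2n/(2n-1) factor
        n = 3
        for i in range(3):
            e_sum = 0.0
            o_hom = 0
            for j in range(4):
                p = g[:, j].sum() / (2 * n)
                e_sum += 1 - 2 * p * (1 - p) * (2 * n) / (2 * n - 1)
                o_hom += g[i, j] != 1
            expected = (o_hom - e_sum) / (4 - e_sum)
            assert out.loc[i, "fis"] == pytest.approx(expected)


# ---------------------------------------------------------------------------
# ROH
# ---------------------------------------------------------------------------

def roh_oracle(codes, pos, min_snps, min_length, max_het, max_missing, max_gap):
    """Exhaustive-window ROH reference: O(n^2) scan over all windows.

    codes: 0 hom, 1 het, 2 missing. Returns (start_idx, end_idx) pairs
    after maximality, minimum filters and greedy overlap resolution.
    """
    n = len(codes)

    def valid(i, j):
        if codes[i] != 0 or codes[j] != 0:
            return False
        window = codes[i : j + 1]
        if (window == 1).sum() > max_het or (window == 2).sum() > max_missing:
            return False
        if np.any(np.diff(pos[i : j + 1]) > max_gap):
            return False
        return True

    windows = [(i, j) for i in range(n) for j in range(i, n) if valid(i, j)]
    maximal = [
        (i, j)
        for (i, j) in windows
        if not any((a <= i and j <= b and (a, b) != (i, j)) for (a, b) in windows)
    ]
    qualified = [
        (i, j)
        for (i, j) in sorted(maximal)
        if (j - i + 1) >= min_snps and (pos[j] - pos[i]) >= min_length
    ]
    chosen = []
    last_end = -1
    for i, j in qualified:
        if i > last_end:
            chosen.append((i, j))
            last_end = j
    return chosen


def _dataset_from_codes(codes, pos):
    g = np.array(
        [{0: 0, 1: 1, 2: MISSING}[int(c)] for c in codes], dtype=np.int8
    )[None, :]
    return make_dataset(g, chrom=["1"] * len(codes), pos=pos)


class TestDetectRoh:
    def test_simple_run(self):
        # 30 homozygous SNPs spanning 2 Mb -> one segment with 30 SNPs
        pos = np.arange(30) * 68_966 + 1  # ~2 Mb span
        ds = _dataset_from_codes(np.zeros(30), pos)
        segs = detect_roh(ds, min_snps=25, min_length_bp=1e6)
        assert len(segs) == 1
        assert segs.iloc[0]["n_snps"] == 30
        assert segs.iloc[0]["length_bp"] == pos[-1] - pos[0]

    def test_all_heterozygous_chromosome(self):
        pos = np.arange(40) * 50_000 + 1
        ds = _dataset_from_codes(np.ones(40), pos)
        assert len(detect_roh(ds)) == 0

    def test_gap_splits_run(self):
        pos = np.concatenate([np.arange(30) * 50_000 + 1,
                              np.arange(30) * 50_000 + 3_000_000])
        ds = _dataset_from_codes(np.zeros(60), pos)
        segs = detect_roh(ds, min_snps=25, min_length_bp=1e6, max_gap_bp=1e6)
        assert len(segs) == 2

    def test_unsorted_input_rejected(self):
        ds = _dataset_from_codes(np.zeros(5), [5000, 1000, 2000, 3000, 4000])
        with pytest.raises(DatasetError):
            detect_roh(ds)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 300
        codes = rng.choice([0, 1, 2], size=n, p=[0.82, 0.12, 0.06])
        pos = np.sort(rng.choice(np.arange(1, 3_000_000), size=n, replace=False))
        params = dict(min_snps=5, min_length=100_000, max_het=1,
                      max_missing=1, max_gap=200_000)
        expected = roh_oracle(codes, pos, **params)
        ds = _dataset_from_codes(codes, pos)
        segs = detect_roh(
            ds, min_snps=params["min_snps"], min_length_bp=params["min_length"],
            max_het=params["max_het"], max_missing=params["max_missing"],
            max_gap_bp=params["max_gap"],
        )
        got = [
            (int(np.flatnonzero(pos == r.start_bp)[0]),
             int(np.flatnonzero(pos == r.end_bp)[0]))
            for r in segs.itertuples(index=False)
        ]
        assert got == expected

    @pytest.mark.parametrize("max_het,max_missing", [(0, 0), (2, 1), (1, 2)])
    def test_oracle_other_budgets(self, max_het, max_missing):
        rng = np.random.default_rng(99)
        n = 200
        codes = rng.choice([0, 1, 2], size=n, p=[0.8, 0.15, 0.05])
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), size=n, replace=False))
        expected = roh_oracle(codes, pos, 4, 50_000, max_het, max_missing, 150_000)
        ds = _dataset_from_codes(codes, pos)
        segs = detect_roh(ds, min_snps=4, min_length_bp=50_000,
                          max_het=max_het, max_missing=max_missing,
                          max_gap_bp=150_000)
        got = [
            (int(np.flatnonzero(pos == r.start_bp)[0]),
             int(np.flatnonzero(pos == r.end_bp)[0]))
            for r in segs.itertuples(index=False)
        ]
        assert got == expected


class TestFroh:
    def test_default_genome_denominator_arithmetic(self):
        segs = pd.DataFrame(
            {
                "sample_id": ["s"],
                "chrom": ["1"],
                "start_bp": [1],
                "end_bp": [261_000_001],
                "n_snps": [1000],
                "length_bp": [261_000_000],
            }
        )
        out = froh(segs, ["s"])
        assert out.loc[0, "froh_all"] == pytest.approx(0.1)

    def test_no_segments(self):
        empty = pd.DataFrame(
            columns=["sample_id", "chrom", "start_bp", "end_bp", "n_snps", "length_bp"]
        )
        out = froh(empty, ["a", "b"])
        assert (out.filter(like="froh").to_numpy() == 0).all()

    def test_class_partition(self, rng):
        lengths = rng.uniform(1e6, 40e6, size=30).astype(int)
        segs = pd.DataFrame(
            {
                "sample_id": "s",
                "chrom": [str(c) for c in range(30)],
                "start_bp": 1,
                "end_bp": lengths + 1,
                "n_snps": 100,
                "length_bp": lengths,
            }
        )
        out = froh(segs, ["s"])
        total = out[["froh_1_5", "froh_5_20", "froh_gt20"]].sum(axis=1)[0]
        assert total == pytest.approx(out.loc[0, "froh_all"], abs=1e-12)

    def test_overlap_rejected(self):
        segs = pd.DataFrame(
            {
                "sample_id": ["s", "s"],
                "chrom": ["1", "1"],
                "start_bp": [1, 500_000],
                "end_bp": [1_000_000, 2_000_000],
                "n_snps": [50, 50],
                "length_bp": [999_999, 1_500_000],
            }
        )
        with pytest.raises(DatasetError, match="overlap"):
            froh(segs, ["s"])
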