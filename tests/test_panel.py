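"""Top-F_ST SNP panels, panel PCA, discriminant LOOCV, assignment grid."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from islandpop.dataset import MISSING
from islandpop.panel import (
    GaussianDiscriminant,
    discriminant_loocv,
    grid_evaluate,
    panel_pca,
    rank_snps_by_fst,
    weighted_overall_error,
)
from islandpop.differentiation import wc_fst
from islandpop.simulate import SimConfig, simulate_dataset

from conftest import make_dataset


@pytest.fixture(scope="module")
def island_cohort():
    cfg = SimConfig(
        n_snps=600,
        herd_sizes={"A": (60,), "B": (40,)},
        fst_island=0.10,
        fst_herd=0.001,
        admixed_fraction=0.0,
        seed=23,
    )
    ds, truth = simulate_dataset(cfg)
    return ds, truth


class TestRanking:
    def test_fixed_difference_ranks_first(self, rng):
        g = rng.binomial(2, 0.5, size=(40, 50)).astype(np.int8)
        g[:20, 7] = 0
        g[20:, 7] = 2  # fixed difference at SNP 7
        ds = make_dataset(g, islands=["A"] * 20 + ["B"] * 20)
        ranked = rank_snps_by_fst(ds, ds.samples["island"])
        assert ranked.iloc[0]["snp_id"] == "snp7"
        assert ranked.iloc[0]["theta"] == pytest.approx(1.0)

    def test_matches_per_snp_recomputation(self, island_cohort):
        ds, _ = island_cohort
        ds200 = ds.subset_snps(np.arange(200))
        ranked = rank_snps_by_fst(ds200, ds200.samples["island"])
        theta_locus, _ = wc_fst(
            ds200, ds200.samples["island"], "A", "B"
        )
        order = np.argsort(-np.nan_to_num(theta_locus, nan=-np.inf), kind="stable")
        assert list(ranked["snp_index"]) == list(order)
        # panel means decrease with panel size
        means = [ranked.head(k)["theta"].mean() for k in (25, 50, 100, 150)]
        assert means == sorted(means, reverse=True)


class TestPanelPca:
    def test_full_decomposition_keeps_variance(self, island_cohort):
        ds, _ = island_cohort
        idx = np.arange(10)
        scores = panel_pca(ds, idx, n_pcs=10)
        # standardized columns: total variance equals column count
        total = scores.var(axis=0, ddof=1).sum()
        assert total == pytest.approx(10.0, rel=1e-9)

    def test_island_separation_on_top_panel(self, island_cohort):
        ds, truth = island_cohort
        ranked = rank_snps_by_fst(ds, ds.samples["island"])
        scores = panel_pca(ds, ranked.head(50)["snp_index"].to_numpy(), n_pcs=2)
        is_a = (truth.samples["island"] == "A").to_numpy().astype(float)
        r = np.corrcoef(scores[:, 0], is_a)[0, 1]
        assert abs(r) > 0.9

    def test_deterministic_sign_convention(self, island_cohort):
        ds, _ = island_cohort
        idx = np.arange(25)
        s1 = panel_pca(ds, idx, 5)
        s2 = panel_pca(ds, idx, 5)
        np.testing.assert_array_equal(s1, s2)

    def test_zero_variance_column_dropped(self, rng):
        g = rng.binomial(2, 0.5, size=(30, 5)).astype(np.int8)
        g[:, 2] = 1
        ds = make_dataset(g)
        with pytest.warns(UserWarning, match="zero-variance"):
            scores = panel_pca(ds, np.arange(5), 4)
        assert scores.shape == (30, 4)

    def test_mean_imputation_of_missing(self, rng):
        g = rng.binomial(2, 0.5, size=(30, 10)).astype(np.int8)
        g[0, 0] = MISSING
        ds = make_dataset(g)
        scores = panel_pca(ds, np.arange(10), 3)
        assert np.isfinite(scores).all()


def loocv_oracle(x, y, pooled):
    """Naive refit-per-sample LOOCV using scipy multivariate normals."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    n = len(y)
    wrong = np.zeros(n, dtype=bool)
    classes = list(pd.unique(y))
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xt, yt = x[mask], y[mask]
        post = {}
        if pooled:
            devs = np.vstack([xt[yt == c] - xt[yt == c].mean(axis=0) for c in classes])
            cov = devs.T @ devs / (len(xt) - len(classes))
        for c in classes:
            xc = xt[yt == c]
            cv = cov if pooled else np.cov(xc, rowvar=False, ddof=1)
            post[c] = multivariate_normal.logpdf(
                x[i], mean=xc.mean(axis=0), cov=np.atleast_2d(cv)
            ) + np.log(len(xc) / len(xt))
        wrong[i] = max(post, key=post.get) != y[i]
    per_class = {c: float(wrong[y == c].mean()) for c in classes}
    return per_class, float(wrong.mean())


class TestDiscriminant:
    @pytest.mark.parametrize("pooled", [False, True])
    def test_loocv_equals_naive_oracle(self, rng, pooled):
        x = np.vstack(
            [
                rng.normal([0, 0], [1.0, 2.0], size=(25, 2)),
                rng.normal([1.5, 0.5], [2.0, 0.7], size=(35, 2)),
            ]
        )
        y = np.array(["a"] * 25 + ["b"] * 35)
        per_class, overall = discriminant_loocv(x, y, pooled=pooled)
        exp_class, exp_overall = loocv_oracle(x, y, pooled)
        assert per_class == exp_class
        assert overall == exp_overall

    def test_separable_clusters_zero_error(self, rng):
        x = np.vstack(
            [
                rng.normal(0.0, 1.0, size=(40, 3)),
                rng.normal(10.0, 1.0, size=(30, 3)),  # 10 SD apart
            ]
        )
        y = np.array(["a"] * 40 + ["b"] * 30)
        per_class, overall = discriminant_loocv(x, y)
        assert overall == 0.0
        assert set(per_class.values()) == {0.0}

    def test_identical_distributions_chance_level(self, rng):
        x = rng.normal(size=(200, 2))
        y = np.array(["a", "b"] * 100)
        _, overall = discriminant_loocv(x, y)
        assert 0.35 < overall < 0.65

    def test_priors_proportional_to_size(self, rng):
        x = np.vstack([rng.normal(0, 1, (80, 1)), rng.normal(0.2, 1, (8, 1))])
        y = np.array(["big"] * 80 + ["small"] * 8)
        clf = GaussianDiscriminant().fit(x, y)
        assert clf.priors_["big"] == pytest.approx(80 / 88)
        # near-identical classes: the prior should dominate predictions
        pred = clf.predict(rng.normal(0.1, 1, (50, 1)))
        assert (pred == "big").mean() > 0.9

    def test_singular_covariance_ridged(self, rng):
        x = np.vstack([rng.normal(size=(3, 5)), rng.normal(2, 1, size=(30, 5))])
        y = np.array(["tiny"] * 3 + ["big"] * 30)
        with pytest.warns(UserWarning, match="singular"):
            clf = GaussianDiscriminant().fit(x, y)
        assert np.isfinite(clf.log_posteriors(x)).all()


class TestWeightedOverallError:
    def test_published_row_arithmetic_25_snp(self):
        # per-class rates 1.95% / 10.26% with class sizes 307 / 117
        assert weighted_overall_error([0.0195, 0.1026], [307, 117]) == pytest.approx(
            0.0425, abs=5e-5
        )

    def test_published_row_arithmetic_50_snp(self):
        assert weighted_overall_error([0.0065, 0.0342], [307, 117]) == pytest.approx(
            0.0142, abs=5e-5
        )

    def test_zero_rates(self):
        assert weighted_overall_error([0.0, 0.0], [300, 100]) == 0.0

    def test_plain_weighted_mean_mode(self):
        got = weighted_overall_error([0.1, 0.3], [3, 1], integer_counts=False)
        assert got == pytest.approx(0.15)

    def test_validation(self):
        with pytest.raises(ValueError):
            weighted_overall_error([0.1], [10, 20])
        with pytest.raises(ValueError):
            weighted_overall_error([1.2, 0.0], [10, 20])


class TestGrid:
    def test_full_grid_shape_and_consistency(self, island_cohort):
        ds, truth = island_cohort
        grid = grid_evaluate(
            ds, panel_sizes=(25, 50, 100, 150), pc_counts=(1, 2, 5, 10)
        )
        assert len(grid) == 16
        sizes = truth.samples["island"].value_counts()
        for _, row in grid.iterrows():
            w = (row["error_A"] * sizes["A"] + row["error_B"] * sizes["B"]) / len(
                truth.samples
            )
            assert row["overall_error"] == pytest.approx(w, abs=1e-12)

    def test_strong_panels_classify_well(self, island_cohort):
        ds, _ = island_cohort
        grid = grid_evaluate(ds, panel_sizes=(150,), pc_counts=(2,))
        assert grid.iloc[0]["overall_error"] <= 0.05

    def test_oversized_panel_skipped(self, island_cohort):
        ds, _ = island_cohort
        with pytest.warns(UserWarning, match="skipped"):
            grid = grid_evaluate(ds, panel_sizes=(10_000, 25), pc_counts=(2,))
        assert set(grid["panel_size"]) == {25}

    def test_reproducible(self, island_cohort):
        ds, _ = island_cohort
        g1 = grid_evaluate(ds, panel_sizes=(25,), pc_counts=(1, 2))
        g2 = grid_evaluate(ds, panel_sizes=(25,), pc_counts=(1, 2))
        pd.testing.assert_frame_equal(g1, g2)
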