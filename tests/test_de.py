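import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panconserv import (
    CountMatrix,
    adjust_bh,
    estimate_dispersions,
    estimate_size_factors,
    pool_insilico,
    standard_endocrine_recipe,
    wald_test,
)
from panconserv.errors import (
    ContractError,
    DegenerateSampleError,
    InsufficientReplicationError,
    RecipeError,
)

from conftest import make_count_matrix, nb_counts


def median_of_ratios_oracle(counts: np.ndarray) -> np.ndarray:
    """Literal median-of-ratios recomputation, no shortcuts shared with the
    implementation."""
    log_geo = np.log(counts).mean(axis=1)
    keep = np.isfinite(log_geo)
    factors = np.array(
        [np.median(counts[keep, j] / np.exp(log_geo[keep])) for j in range(counts.shape[1])]
    )
    return factors / np.exp(np.mean(np.log(factors)))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = make_count_matrix(np.tile([[4], [9], [1]], (1, 2)), ["a", "a"])
        np.testing.assert_allclose(estimate_size_factors(cm), [1.0, 1.0])

    def test_doubled_sample_under_geometric_mean_one(self):
        base = np.array([[10], [20], [30]])
        cm = make_count_matrix(np.hstack([base, 2 * base]), ["a", "b"])
        np.testing.assert_allclose(
            estimate_size_factors(cm), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_median_of_ratios(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 500, size=(50, 6))
        counts[:10] = rng.integers(1, 500, size=(10, 6))  # ensure positive geomeans
        cm = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        np.testing.assert_allclose(
            estimate_size_factors(cm).to_numpy(),
            median_of_ratios_oracle(counts.astype(float)),
            rtol=1e-10,
        )

    def test_geometric_mean_is_one(self, two_condition_matrix):
        sf = estimate_size_factors(two_condition_matrix)
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-9)

    def test_normalization_idempotence(self, two_condition_matrix):
        """Size factors of an already-normalized matrix are 1 within rounding."""
        cm = two_condition_matrix
        sf = estimate_size_factors(cm)
        normalized = np.rint(cm.counts.to_numpy() / sf.to_numpy()[None, :]).astype(int)
        cm2 = make_count_matrix(normalized, ["a"] * 3 + ["b"] * 3)
        assert np.allclose(estimate_size_factors(cm2), 1.0, atol=0.05)

    def test_all_zero_gene_overlap_raises(self):
        counts = np.array([[0, 5], [3, 0]])
        cm = make_count_matrix(counts, ["a", "b"])
        with pytest.raises(DegenerateSampleError):
            estimate_size_factors(cm)


class TestDispersions:
    def test_constant_gene_gets_floor(self):
        counts = np.vstack([np.full(6, 40), nb_counts(np.random.default_rng(0), 100, 0.5, (20, 6))])
        cm = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersions(cm, sf)
        assert disp.alpha.iloc[0] == pytest.approx(1e-8)
        assert disp.status.iloc[0] == "floored"

    def test_all_zero_gene_flagged(self):
        counts = np.vstack([np.zeros(6, dtype=int), nb_counts(np.random.default_rng(1), 100, 0.2, (20, 6))])
        cm = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        disp = estimate_dispersions(cm, estimate_size_factors(cm))
        assert disp.status.iloc[0] == "all_zero"
        assert np.isnan(disp.alpha.iloc[0])

    def test_simulation_recovery_mu200_alpha02(self):
        """Median estimate over replicated genes lands within 25% of the truth
        at n=50."""
        rng = np.random.default_rng(5)
        counts = nb_counts(rng, 200.0, 0.2, (300, 50))
        cm = make_count_matrix(counts, ["a"] * 25 + ["b"] * 25)
        disp = estimate_dispersions(cm, estimate_size_factors(cm))
        est = disp.alpha[disp.status == "estimated"]
        assert 0.15 < est.median() < 0.25

    def test_all_singleton_groups_raise(self):
        cm = make_count_matrix(np.ones((3, 2), dtype=int), ["a", "b"])
        with pytest.raises(InsufficientReplicationError):
            estimate_dispersions(cm, pd.Series(1.0, index=cm.sample_ids))


class TestWaldTest:
    def test_identical_conditions_give_zero_fc_p_one(self):
        block = nb_counts(np.random.default_rng(2), 200, 0.1, (30, 3))
        cm = make_count_matrix(np.hstack([block, block]), ["a"] * 3 + ["b"] * 3)
        sf = pd.Series(1.0, index=cm.sample_ids)
        disp = estimate_dispersions(cm, sf)
        de = wald_test(cm, sf, disp, (cm.sample_ids[:3], cm.sample_ids[3:]))
        tested = de[de["tested"]]
        assert (tested["log2fc"] == 0.0).all()
        assert (tested["p"] == 1.0).all()

    def test_swapping_conditions_negates_log2fc_preserves_p(self, two_condition_matrix):
        cm = two_condition_matrix
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        a, b = cm.sample_ids[:3], cm.sample_ids[3:]
        de_ab = wald_test(cm, sf, disp, (a, b))
        de_ba = wald_test(cm, sf, disp, (b, a))
        tested = de_ab["tested"].to_numpy()
        np.testing.assert_allclose(
            de_ab.loc[tested, "log2fc"], -de_ba.loc[tested, "log2fc"], atol=1e-9
        )
        np.testing.assert_allclose(de_ab.loc[tested, "p"], de_ba.loc[tested, "p"], atol=1e-12)

    def test_planted_sixteen_fold_recovery(self):
        """Planted 16-fold genes: mean recovered log2fc within 0.3 of 4 and
        rejection rate >= 0.95 at the adjusted threshold (200 planted genes)."""
        rng = np.random.default_rng(3)
        n_pl, n_bg = 200, 1000
        mu = np.full((n_pl + n_bg, 8), 100.0)
        mu[:n_pl, :4] *= 16
        cm = make_count_matrix(nb_counts(rng, mu, 0.05, mu.shape), ["a"] * 4 + ["b"] * 4)
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        de = wald_test(cm, sf, disp, (cm.sample_ids[:4], cm.sample_ids[4:]))
        planted = de.iloc[:n_pl]
        assert abs(planted["log2fc"].mean() - 4.0) < 0.3
        rejected = (planted["p_adj"] < 0.05) & (planted["log2fc"] > 2.0)
        assert rejected.mean() >= 0.95

    def test_unknown_sample_in_contrast(self, two_condition_matrix):
        cm = two_condition_matrix
        sf = estimate_size_factors(cm)
        disp = estimate_dispersions(cm, sf)
        with pytest.raises(ContractError):
            wald_test(cm, sf, disp, (["nope"], cm.sample_ids[3:]))

    def test_low_expression_genes_not_tested(self):
        rng = np.random.default_rng(9)
        counts = nb_counts(rng, 300, 0.1, (100, 6))
        counts[:5] = rng.poisson(0.5, size=(5, 6))  # far below the filter
        cm = make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
        sf = estimate_size_factors(cm)
        de = wald_test(cm, sf, estimate_dispersions(cm, sf), (cm.sample_ids[:3], cm.sample_ids[3:]))
        low = de.iloc[:5]
        assert (~low["tested"]).all()
        assert low["p"].isna().all() and low["p_adj"].isna().all()


def bh_oracle(p):
    """Direct step-up: find largest k with p_(k) <= k*q/n, by scanning."""
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        adj[order[rank - 1]] = running
    return adj


class TestAdjustBH:
    def test_forced_example(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(adjust_bh(np.array([0.2])), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            adjust_bh(np.array([0.5, 1.5]))
        with pytest.raises(ContractError):
            adjust_bh(np.array([0.5, np.nan]))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_independent_step_up(self, p):
        p = np.array(p)
        np.testing.assert_allclose(adjust_bh(p), bh_oracle(p), rtol=1e-12, atol=1e-15)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p(self, p):
        """p_adj is a non-decreasing function of p within one family."""
        p = np.array(p)
        adj = adjust_bh(p)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(0)
        p = rng.uniform(size=500)
        np.testing.assert_allclose(adjust_bh(p), multipletests(p, method="fdr_bh")[1], rtol=1e-12)


class TestPooling:
    def test_paired_replicate_recipe(self):
        """Composite #i sums replicate i of alpha, beta and delta."""
        rng = np.random.default_rng(4)
        cm = make_count_matrix(
            rng.integers(0, 100, (20, 9)),
            ["alpha"] * 3 + ["beta"] * 3 + ["delta"] * 3,
        )
        recipe = standard_endocrine_recipe(cm)
        assert [r[0] for r in recipe] == [f"zebrafish_endocrine{i}" for i in (1, 2, 3)]
        pooled = pool_insilico(cm, recipe)
        assert pooled.n_samples == 3
        expected = (
            cm.counts[["s0", "s3", "s6"]].sum(axis=1)  # replicate 1 of each subtype
        )
        pd.testing.assert_series_equal(
            pooled.counts["zebrafish_endocrine1"], expected, check_names=False
        )
        assert set(pooled.samples["cell_type"]) == {"endocrine"}

    def test_total_counts_conserved_exactly(self):
        rng = np.random.default_rng(5)
        cm = make_count_matrix(rng.integers(0, 10**7, (10, 6)), ["a"] * 3 + ["b"] * 3)
        pooled = pool_insilico(cm, [("p1", "pool", ["s0", "s3"]), ("p2", "pool", ["s1", "s4"])])
        assert (pooled.counts["p1"] == cm.counts["s0"] + cm.counts["s3"]).all()
        assert pooled.counts[["p1", "p2"]].to_numpy().sum() == cm.counts[["s0", "s3", "s1", "s4"]].to_numpy().sum()

    def test_all_zero_pooling(self):
        cm = make_count_matrix(np.zeros((5, 4), dtype=int), ["a", "a", "b", "b"])
        pooled = pool_insilico(cm, [("p1", "pool", ["s0", "s2"])])
        assert (pooled.counts["p1"] == 0).all()

    def test_overlapping_constituents_rejected(self):
        cm = make_count_matrix(np.ones((3, 4), dtype=int), ["a", "a", "b", "b"])
        with pytest.raises(RecipeError):
            pool_insilico(cm, [("p1", "x", ["s0", "s1"]), ("p2", "x", ["s1", "s2"])])

    def test_unknown_constituent_rejected(self):
        cm = make_count_matrix(np.ones((3, 2), dtype=int), ["a", "b"])
        with pytest.raises(ContractError):
            pool_insilico(cm, [("p1", "x", ["s0", "missing"])])
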