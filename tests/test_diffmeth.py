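import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from msrecount.diffmeth import (
    DiffMethError,
    NormFactors,
    bh_adjust,
    build_design,
    diff_meth,
    estimate_dispersions,
    exact_test_two_group,
    filter_low_mask,
    glm_lrt,
    tmm_norm_factors,
)
from msrecount.simulate import simulate_count_matrix

# Hand-written 8-site x 6-sample count matrix with a dominant site in the
# second condition; reference values below were computed independently with
# edgeR 4.0.16 (calcNormFactors TMM, exactTestDoubleTail, glmFit/glmLRT at
# fixed dispersion 0.15, offsets log(1000), prior.count 0).
FIXTURE = np.array(
    [
        [12, 10, 35, 4, 16, 8],
        [100, 80, 2, 120, 90, 110],
        [55, 60, 48, 52, 58, 61],
        [3, 0, 5, 2, 1, 4],
        [40, 42, 38, 160, 150, 155],
        [9, 14, 11, 10, 13, 12],
        [200, 180, 210, 190, 205, 195],
        [1, 2, 0, 3, 1, 2],
    ],
    dtype=float,
)
EDGER_TMM = [1.0626717187, 1.0745033232, 1.3177245261,
             0.8809806967, 0.8676353922, 0.8694904837]
EDGER_EXACT_P = [0.0816186452, 0.0928695600, 0.9009271841, 1.0,
                 0.0000842563, 1.0, 1.0, 0.5511639975]
EDGER_GLM_P = [0.0690310439, 0.0884284301, 0.8861520691, 0.8256353513,
               0.0000718905, 0.9418616274, 1.0, 0.3606565391]
EDGER_GLM_LOGFC = [-1.0255350921, 0.8141334547, 0.0691243607, -0.1926450779,
                   1.9541963104, 0.0418201757, 0.0, 1.0]

EQ_NORM = NormFactors(factors=np.ones(6), lib_sizes=np.full(6, 1000.0))
TWO_GROUP_DESIGN = np.column_stack([np.ones(6), [0, 0, 0, 1, 1, 1]])


class TestFilterLow:
    def test_zero_rows_removed(self):
        counts = np.array([[0, 0, 0], [2, 0, 0], [5, 5, 5]])
        lib = np.full(3, 1e6)
        assert filter_low_mask(counts, lib, 1.0, 1).tolist() == [False, True, True]

    def test_threshold_zero_keeps_any_nonzero(self):
        counts = np.array([[0, 0], [1, 0]])
        assert filter_low_mask(counts, np.full(2, 1e6), 0.0, 1).tolist() == [False, True]

    def test_min_samples_rule(self):
        # CPM = (2, 0, 0) at library size 1e6: above 1 in only one sample
        counts = np.array([[2, 0, 0]])
        assert filter_low_mask(counts, np.full(3, 1e6), 1.0, 2).tolist() == [False]

    def test_min_samples_bounds(self):
        with pytest.raises(DiffMethError):
            filter_low_mask(np.ones((2, 3)), np.full(3, 1e6), 1.0, 4)


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.array([10.0, 50, 3, 80, 22, 7])
        nf = tmm_norm_factors(np.column_stack([col, col, col]))
        assert np.allclose(nf.factors, 1.0, atol=1e-12)

    def test_scale_invariance(self):
        # one column a constant multiple of another: identical count
        # fractions, so both factors are 1
        col = np.array([10.0, 50, 3, 80, 22, 7])
        nf = tmm_norm_factors(np.column_stack([col, 3 * col]))
        assert np.allclose(nf.factors, 1.0, atol=1e-12)

    def test_multiplying_one_sample_leaves_factors_nearly_unchanged(self):
        # count fractions, M values and trimming are exactly invariant under
        # a constant rescaling of one column; only the precision weights of
        # that column shrink, so factors move by a negligible amount
        rng = np.random.default_rng(8)
        y = rng.poisson(30, (100, 4)).astype(float)
        f1 = tmm_norm_factors(y).factors
        y2 = y.copy()
        y2[:, 2] *= 7
        f2 = tmm_norm_factors(y2).factors
        assert np.allclose(f1, f2, atol=5e-3)

    def test_matches_edger_reference_implementation(self):
        nf = tmm_norm_factors(FIXTURE)
        assert np.allclose(nf.factors, EDGER_TMM, atol=1e-9)
        assert abs(np.exp(np.mean(np.log(nf.factors))) - 1) < 1e-12

    def test_no_shared_positive_site_is_error(self):
        y = np.array([[5.0, 0], [3, 0], [0, 4]])
        with pytest.raises(DiffMethError, match="normalization"):
            tmm_norm_factors(y)


class TestExactTest:
    def test_balanced_split_has_p_one(self):
        # (3,3) of t=6 at equal sizes, dispersion 0: the observed split is
        # the conditional mode, so every outcome qualifies
        y = np.array([[1.0, 1, 1, 1, 1, 1]])
        p = exact_test_two_group(y, EQ_NORM, list("aaabbb"), 0.0)
        assert p[0] == pytest.approx(1.0)

    def test_extreme_split_enumeration(self):
        # (6,0) of t=6: only the two extreme outcomes have probability
        # <= observed, p = 2 * (1/2)^6
        y = np.array([[2.0, 2, 2, 0, 0, 0]])
        p = exact_test_two_group(y, EQ_NORM, list("aaabbb"), 0.0)
        assert p[0] == pytest.approx(2 * 0.5**6)

    def test_group_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        y = rng.poisson(20, (30, 6)).astype(float)
        p1 = exact_test_two_group(y, EQ_NORM, list("aaabbb"), 0.1)
        p2 = exact_test_two_group(y, EQ_NORM, list("bbbaaa"), 0.1)
        assert np.allclose(p1, p2, atol=1e-12)

    def test_matches_edger_conditional_test(self):
        p = exact_test_two_group(FIXTURE, EQ_NORM, list("aaabbb"), 0.15)
        assert np.allclose(p, EDGER_EXACT_P, atol=1e-8)

    def test_three_groups_rejected(self):
        with pytest.raises(DiffMethError, match="glm"):
            exact_test_two_group(FIXTURE, EQ_NORM, list("aabbcc"), 0.1)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(DiffMethError):
            exact_test_two_group(FIXTURE, EQ_NORM, list("aaabbb"), -0.1)

    def test_null_p_values_stochastically_conservative(self):
        """Under the null at known dispersion, the discrete conditional test
        is conservative: P(p <= a) <= a (within sampling error)."""
        rng = np.random.default_rng(77)
        sim = simulate_count_matrix(
            10_000, rng, n_per_group=(6, 6), mean_count=50, dispersion=0.1
        )
        y = sim["counts"].astype(float)
        norm = NormFactors(np.ones(12), y.sum(axis=0))
        p = exact_test_two_group(y, norm, sim["groups"], 0.1)
        for a in (0.01, 0.05, 0.10, 0.25):
            assert np.mean(p <= a) <= a + 0.01


class TestDispersionEstimation:
    def test_recovery_of_true_dispersion(self):
        rng = np.random.default_rng(11)
        sim = simulate_count_matrix(
            500, rng, n_per_group=(6, 6), mean_count=100, dispersion=0.1
        )
        design = np.column_stack([np.ones(12), [0] * 6 + [1] * 6])
        common, tagwise = estimate_dispersions(sim["counts"], design)
        assert 0.07 <= common <= 0.13
        assert np.all(tagwise >= 0)

    def test_large_prior_df_shrinks_tagwise_to_common(self):
        rng = np.random.default_rng(12)
        sim = simulate_count_matrix(
            100, rng, n_per_group=(4, 4), mean_count=80, dispersion=0.1
        )
        design = np.column_stack([np.ones(8), [0] * 4 + [1] * 4])
        common, tagwise = estimate_dispersions(sim["counts"], design, prior_df=1e8)
        assert np.allclose(tagwise, common, rtol=0.05)

    def test_poisson_data_gives_near_zero_dispersion(self):
        rng = np.random.default_rng(13)
        sim = simulate_count_matrix(
            400, rng, n_per_group=(6, 6), mean_count=100, dispersion=0.0
        )
        design = np.column_stack([np.ones(12), [0] * 6 + [1] * 6])
        common, _ = estimate_dispersions(sim["counts"], design)
        assert common <= 0.01

    def test_saturated_design_is_error(self):
        with pytest.raises(DiffMethError):
            estimate_dispersions(np.ones((5, 2)), np.eye(2))


class TestGlmLrt:
    def test_matches_edger_fixture(self):
        res = glm_lrt(FIXTURE, TWO_GROUP_DESIGN, 1, EQ_NORM, 0.15)
        assert np.allclose(res.p_value, EDGER_GLM_P, atol=1e-6)
        assert np.allclose(res.logFC, EDGER_GLM_LOGFC, atol=1e-6)

    def test_flat_site_has_zero_logfc_p_one(self):
        y = np.array([[20.0] * 6])
        res = glm_lrt(y, TWO_GROUP_DESIGN, 1, EQ_NORM, 0.1)
        assert abs(res.logFC[0]) < 1e-8
        assert res.p_value[0] > 0.999

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(21)
        sim = simulate_count_matrix(
            1000, rng, n_per_group=(6, 6), mean_count=100, dispersion=0.1
        )
        y = sim["counts"]
        norm = tmm_norm_factors(y)
        design = np.column_stack([np.ones(12), [0] * 6 + [1] * 6])
        _, tagwise = estimate_dispersions(y, design, np.log(norm.effective_sizes))
        res = glm_lrt(y, design, 1, norm, tagwise)
        frac = np.mean(res.p_value < 0.05)
        assert 0.03 <= frac <= 0.07

    def test_rank_correlates_with_exact_test(self):
        rng = np.random.default_rng(22)
        sim = simulate_count_matrix(
            300, rng, n_per_group=(5, 5), mean_count=60, dispersion=0.1,
            dm_fraction=0.2, effect_fold=3.0,
        )
        y = sim["counts"].astype(float)
        norm = NormFactors(np.ones(10), np.full(10, float(y.sum(axis=0).mean())))
        design = np.column_stack([np.ones(10), [0] * 5 + [1] * 5])
        res = glm_lrt(y, design, 1, norm, 0.1)
        p_exact = exact_test_two_group(y, norm, sim["groups"], 0.1)
        rho = stats.spearmanr(res.p_value, p_exact).statistic
        assert rho > 0.95

    def test_non_nested_designs_rejected(self):
        with pytest.raises(DiffMethError):
            glm_lrt(FIXTURE, np.column_stack([np.ones(6), np.ones(6)]), 0, EQ_NORM, 0.1)

    def test_blocking_restores_calibration(self):
        """Site-level litter effects with skewed litter-to-group allocation:
        modelling the block keeps type-I error nominal, ignoring it inflates."""
        fr_b, fr_n = [], []
        for seed in (101, 102):
            rng = np.random.default_rng(seed)
            sim = simulate_count_matrix(
                800, rng, n_per_group=(6, 6), mean_count=100, dispersion=0.05,
                block_sd=0.5,
            )
            y = sim["counts"]
            meta = pd.DataFrame(
                {"sample": [f"s{i}" for i in range(12)], "group": sim["groups"],
                 "block": sim["blocks"]}
            )
            xb, names, _ = build_design(meta, "g1", "g2", block="block")
            x = np.column_stack([np.ones(12), [0] * 6 + [1] * 6])
            norm = tmm_norm_factors(y)
            off = np.log(norm.effective_sizes)
            _, tw_b = estimate_dispersions(y, xb, off)
            _, tw = estimate_dispersions(y, x, off)
            fr_b.append(np.mean(
                glm_lrt(y, xb, names.index("group_g2"), norm, tw_b).p_value < 0.05
            ))
            fr_n.append(np.mean(glm_lrt(y, x, 1, norm, tw).p_value < 0.05))
        assert 0.03 <= np.mean(fr_b) <= 0.07
        assert np.mean(fr_n) > np.mean(fr_b)


class TestBhAdjust:
    def test_stepup_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(DiffMethError):
            bh_adjust([0.5, 1.5])

    def test_nan_propagates_without_affecting_others(self):
        out = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_adjust([0.01, 0.04]))

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_preserves_order(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = bh_adjust(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(ours[order]) >= -1e-12)


class TestDiffMethWrapper:
    def make_table(self, sim, blocks=False):
        from msrecount.counts import CutSiteCountTable

        counts = sim["counts"]
        n = counts.shape[1]
        samples = [f"s{i}" for i in range(n)]
        meta = pd.DataFrame({"sample": samples, "group": sim["groups"]})
        if blocks:
            meta["block"] = sim["blocks"]
        sites = pd.DataFrame(
            {"contig": "chr1", "position": np.arange(1, len(counts) + 1) * 50,
             "strand": "+"}
        )
        return CutSiteCountTable(
            sites=sites, counts=counts, samples=samples, sample_meta=meta
        )

    def test_recovers_planted_differential_sites(self):
        rng = np.random.default_rng(30)
        sim = simulate_count_matrix(
            400, rng, n_per_group=(6, 6), mean_count=100, dispersion=0.1,
            dm_fraction=0.1, effect_fold=4.0,
        )
        table = self.make_table(sim)
        res = diff_meth(table, "g1", "g2")
        # sites dropped by the low-count filter are simply not called
        by_pos = res.set_index("position")["fdr"]
        fdr = by_pos.reindex(np.arange(1, 401) * 50).to_numpy()
        sig = np.nan_to_num(fdr, nan=1.0) < 0.05
        dm = sim["dm_flags"]
        assert (sig & dm).sum() / dm.sum() >= 0.8
        assert (sig & ~dm).sum() / max(sig.sum(), 1) <= 0.15

    def test_glm_and_exact_agree_on_two_group_design(self):
        rng = np.random.default_rng(31)
        sim = simulate_count_matrix(
            150, rng, n_per_group=(4, 4), mean_count=80, dispersion=0.1
        )
        table = self.make_table(sim)
        r1 = diff_meth(table, "g1", "g2", method="exact").set_index("position")
        r2 = diff_meth(table, "g1", "g2", method="glm").set_index("position")
        shared = r1.index.intersection(r2.index)
        rho = stats.spearmanr(
            r1.loc[shared, "p_value"], r2.loc[shared, "p_value"]
        ).statistic
        assert rho > 0.9

    def test_unknown_condition_is_error(self):
        rng = np.random.default_rng(32)
        sim = simulate_count_matrix(20, rng, n_per_group=(3, 3), mean_count=50)
        with pytest.raises(DiffMethError):
            diff_meth(self.make_table(sim), "g1", "nope")
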