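"""Inference layer: covariate adjustment, permutation test, FDR,
correlations, effect sizes, classical tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prepostnet.stats import (adjust_for_covariates, bh_fdr,
                              classify_significance, effect_size_from_r,
                              levene_test, metric_cognition_correlation,
                              paired_permutation_test,
                              paired_permutation_test_matrix,
                              residualize_covariates, two_sample_t,
                              two_sample_t_from_data, two_way_anova)

# the printed correlation / effect-size pairs of the emulated study's
# brain-behavior table (n = 26)
TABLE2_R_D = [
    (0.402, 0.878), (-0.381, 0.824), (0.350, 0.747), (-0.427, 0.944),
    (-0.357, 0.764), (0.364, 0.782), (0.350, 0.747), (-0.413, 0.907),
    (0.523, 1.227), (-0.333, 0.706), (-0.385, 0.834),
]


class TestResidualize:
    def _demo(self, rng, n):
        age = rng.uniform(20, 55, n)
        sex = rng.choice(["M", "F"], n)
        return age, sex

    def test_residuals_sum_to_zero_and_orthogonal(self):
        rng = np.random.default_rng(0)
        age, sex = self._demo(rng, 40)
        v = rng.normal(size=40)
        r = residualize_covariates(v, age, sex)
        assert abs(r.sum()) < 1e-8
        assert abs(r @ age) < 1e-6
        sex01 = (sex == "M").astype(float)
        assert abs(r @ sex01) < 1e-8

    def test_perfect_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        age, sex = self._demo(rng, 30)
        r = residualize_covariates(2.0 * age, age, sex)
        assert np.abs(r).max() < 1e-8

    def test_independent_values_stay_near_centered(self):
        rng = np.random.default_rng(2)
        age, sex = self._demo(rng, 1000)
        v = rng.normal(size=1000)
        r = residualize_covariates(v, age, sex)
        assert np.abs(r - (v - v.mean())).max() < 0.05

    def test_single_sex_constant_age_rank_failure(self):
        with pytest.raises(ValueError):
            residualize_covariates(np.arange(6.0), np.full(6, 30.0),
                                   ["F"] * 6)

    def test_adjustment_preserves_mean(self):
        rng = np.random.default_rng(3)
        age, sex = self._demo(rng, 25)
        v = rng.normal(loc=1.7, size=25) + 0.1 * age
        a = adjust_for_covariates(v, age, sex)
        assert a.mean() == pytest.approx(v.mean())
        # and the age slope is removed
        assert abs(np.corrcoef(a, age)[0, 1]) < \
            abs(np.corrcoef(v, age)[0, 1])


class TestPairedPermutation:
    def test_identical_sessions_give_p_one(self):
        x = np.random.default_rng(0).normal(size=10)
        obs, p = paired_permutation_test(x, x, n_perm=200, seed=1)
        assert obs == 0.0 and p == 1.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        pre, post = rng.normal(size=12), rng.normal(size=12)
        r1 = paired_permutation_test(pre, post, n_perm=500, seed=9)
        r2 = paired_permutation_test(pre, post, n_perm=500, seed=9)
        assert r1 == r2

    def test_matches_exhaustive_enumeration_at_n5(self):
        # exact p from all 2^5 sign patterns; Monte-Carlo estimate must
        # land within ~4 binomial SEs
        rng = np.random.default_rng(4)
        diffs = rng.normal(0.8, 1.0, size=5)
        obs = diffs.mean()
        null = [np.mean(diffs * np.array(s))
                for s in itertools.product([1, -1], repeat=5)]
        p_exact = np.mean(np.abs(null) >= abs(obs))
        n_perm = 20_000
        _, p_mc = paired_permutation_test(np.zeros(5), diffs,
                                          n_perm=n_perm, seed=2)
        se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
        assert abs(p_mc - p_exact) < 4 * se + 2 / n_perm

    def test_shared_flips_matrix_matches_single_column(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(size=(10, 4))
        obs, p = paired_permutation_test_matrix(diffs, 300, seed=3)
        o0, p0 = paired_permutation_test_matrix(diffs[:, [0]], 300, seed=3)
        assert obs[0] == o0[0] and p[0] == p0[0]

    def test_effect_detected(self):
        rng = np.random.default_rng(6)
        pre = rng.normal(size=20)
        post = pre + 1.0 + rng.normal(scale=0.3, size=20)
        _, p = paired_permutation_test(pre, post, n_perm=2000, seed=4)
        assert p < 0.01


class TestBHFDR:
    def test_hand_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_invalid_inputs_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan, 0.1]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(1, 40))
    def test_matches_statsmodels_and_dominates_raw(self, seed, m):
        from statsmodels.stats.multitest import multipletests
        p = np.random.default_rng(seed).uniform(1e-6, 1.0, size=m)
        adj = bh_fdr(p)
        _, ref, *_ = multipletests(p, method="fdr_bh")
        assert np.abs(adj - ref).max() < 1e-12
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)


class TestEffectSize:
    @pytest.mark.parametrize("r,d", TABLE2_R_D)
    def test_reproduces_printed_effect_sizes(self, r, d):
        assert round(effect_size_from_r(r), 3) == d

    def test_zero_r_gives_zero(self):
        assert effect_size_from_r(0.0) == 0.0

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            effect_size_from_r(1.0)


class TestMetricCognitionCorrelation:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        res = metric_cognition_correlation(x, 3 * x)
        assert res.r == pytest.approx(1.0)

    def test_null_rejection_rate_at_n26(self):
        # |r| > 0.388 in about 5% of independent draws at n = 26
        rng = np.random.default_rng(7)
        n_rep = 4000
        x = rng.normal(size=(n_rep, 26))
        y = rng.normal(size=(n_rep, 26))
        xz = (x - x.mean(1, keepdims=True)) / x.std(1, keepdims=True)
        yz = (y - y.mean(1, keepdims=True)) / y.std(1, keepdims=True)
        r = (xz * yz).mean(axis=1)
        rate = np.mean(np.abs(r) > 0.388)
        assert 0.035 < rate < 0.065

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            metric_cognition_correlation(np.ones(5), np.arange(5.0))

    def test_recovers_generating_correlation(self):
        # the generator couples score change to the realized betweenness
        # change at the effect nodes with true r ~ 0.5; the pooled sample
        # r over several cohorts must sit inside that value's 95% CI
        from prepostnet.cohort import CohortConfig, generate_cohort
        from prepostnet.metrics import metric_curve_matrices
        from prepostnet.network import (build_threshold_space,
                                        correlation_matrix)
        space = build_threshold_space(0.05, 0.40, 0.05)
        s = np.asarray(space.values)
        xs, ys = [], []
        for seed in range(5):
            cfg = CohortConfig(seed=seed)
            ts, _, behavior = generate_cohort(cfg)
            by = {(t.subject_id, t.session): t for t in ts}
            fiq = behavior.wide("FIQ")
            for sid in sorted({t.subject_id for t in ts}):
                aucs = {}
                for ses in ("pre", "post"):
                    data = by[(sid, ses)].data[cfg.n_discard:]
                    conn = correlation_matrix(
                        by[(sid, ses)].__class__(sid, ses, data,
                                                 by[(sid, ses)].region_labels))
                    mats = metric_curve_matrices(conn, space)
                    aucs[ses] = np.trapezoid(
                        mats["betweenness"][:, [0, 18]], s, axis=0).mean()
                xs.append(aucs["post"] - aucs["pre"])
                ys.append(fiq.loc[sid, "post"] - fiq.loc[sid, "pre"])
        r = np.corrcoef(xs, ys)[0, 1]
        # generating correlation implied by the coupling model
        # y = beta * x + noise with known beta and noise SD
        beta = CohortConfig().behavior_beta
        noise_sd = CohortConfig().behavior_noise_sd
        sx = np.std(xs)
        rho = beta * sx / np.hypot(beta * sx, noise_sd)
        # Fisher-z comparison at n = 150 (slack for the coarse coupling grid)
        z = np.arctanh([r, rho])
        assert abs(z[0] - z[1]) < 2.5 / np.sqrt(len(xs) - 3)


class TestTwoSampleT:
    def test_fiq_pretest_summaries(self):
        t, p = two_sample_t(120.833, 9.021, 30, 118.333, 8.924, 21)
        assert round(t, 3) == 0.978
        assert p > 0.05

    def test_mq_pretest_summaries(self):
        t, _ = two_sample_t(120.367, 9.967, 30, 118.600, 14.080, 20)
        assert round(t, 3) == 0.520

    def test_identical_groups_give_zero(self):
        t, p = two_sample_t(5.0, 1.0, 10, 5.0, 1.0, 12)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_summary_form_equals_raw_form(self):
        rng = np.random.default_rng(8)
        x1, x2 = rng.normal(size=25), rng.normal(0.4, 1.3, size=18)
        t_raw, p_raw = two_sample_t_from_data(x1, x2)
        t_sum, p_sum = two_sample_t(x1.mean(), x1.std(ddof=1), 25,
                                    x2.mean(), x2.std(ddof=1), 18)
        assert t_raw == pytest.approx(t_sum, abs=1e-12)
        assert p_raw == pytest.approx(p_sum, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t(1, 1, 1, 1, 1, 10)
        with pytest.raises(ValueError):
            two_sample_t(1, 0, 10, 1, 1, 10)


class TestLevene:
    def test_shifted_copy_has_equal_spread(self):
        x = np.random.default_rng(9).normal(size=30)
        f, p = levene_test(x, x + 5.0)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_inflated_variance_detected(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=30)
        f, p = levene_test(x, 3 * (x - x.mean()))
        assert p < 0.01


class TestTwoWayAnova:
    def _layout(self, n_per_cell):
        treat, time = [], []
        for g in ("CG", "control"):
            for s in ("pre", "post"):
                treat += [g] * n_per_cell
                time += [s] * n_per_cell
        return treat, time

    def test_equal_cell_means_give_zero_f(self):
        treat, time = self._layout(5)
        rng = np.random.default_rng(11)
        base = rng.normal(size=5)
        scores = np.tile(base, 4)       # identical cells
        table = two_way_anova(scores, treat, time)
        assert np.allclose(table["F"], 0.0, atol=1e-20)

    def test_crossing_interaction_dominates(self):
        treat, time = self._layout(30)
        rng = np.random.default_rng(12)
        cell_mean = {("CG", "pre"): 1.0, ("CG", "post"): -1.0,
                     ("control", "pre"): -1.0, ("control", "post"): 1.0}
        scores = np.array([cell_mean[(g, s)] for g, s in zip(treat, time)]) \
            + rng.normal(scale=0.5, size=120)
        table = two_way_anova(scores, treat, time)
        assert table.loc["Treatment x Time", "F"] == table["F"].max()
        assert table.loc["Treatment x Time", "p"] < 1e-6

    def test_main_effect_recovered(self):
        treat, time = self._layout(40)
        rng = np.random.default_rng(13)
        scores = rng.normal(size=160) + \
            np.where(np.array(treat) == "CG", 1.0, 0.0)
        table = two_way_anova(scores, treat, time)
        assert table.loc["Treatment", "p"] < 1e-4
        assert table.loc["Treatment x Time", "p"] > 0.01

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova([1.0, 2.0, 3.0, 4.0],
                          ["CG", "CG", "control", "control"],
                          ["pre", "pre", "pre", "pre"])


class TestClassifySignificance:
    @pytest.mark.parametrize("p,label", [
        (0.020, "significant"), (0.071, "marginal"), (0.5, "none"),
        (0.05, "marginal"), (0.1, "none"), (0.049999, "significant"),
    ])
    def test_boundaries(self, p, label):
        assert classify_significance(p) == label
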