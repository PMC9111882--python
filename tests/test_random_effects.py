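import numpy as np
import pytest
from statsmodels.stats.meta_analysis import combine_effects

from _oracles import reml_grid_search
from conftest import make_estimates, random_meta
from drinkmeta.random_effects import (
    MetaAnalysisError,
    estimate_tau2,
    fit_random_effects,
    heterogeneity,
    leave_one_out,
)


class TestFitRandomEffects:
    def test_identical_estimates_closed_form(self):
        ests = make_estimates([0.1] * 5, [0.05] * 5)
        fit = fit_random_effects(ests)
        assert fit.pooled == pytest.approx(0.1)
        assert fit.tau2 == 0.0
        assert fit.se_pooled == pytest.approx(0.05 / np.sqrt(5))
        assert fit.ci_low == pytest.approx(0.056174, abs=1e-6)
        assert fit.ci_high == pytest.approx(0.143826, abs=1e-6)
        assert fit.Q == pytest.approx(0.0, abs=1e-12)
        assert fit.I2 == pytest.approx(0.0)

    def test_symmetric_pair_pools_to_zero(self):
        fit = fit_random_effects(make_estimates([-0.1, 0.1], [0.04, 0.04]))
        assert fit.pooled == pytest.approx(0.0, abs=1e-12)

    def test_reml_matches_grid_search_oracle(self, rng):
        # brute-force restricted-likelihood maximiser on a 7-study toy set
        y, v = random_meta(rng, k=7)
        ests = make_estimates(y, np.sqrt(v))
        fit = fit_random_effects(ests, method="REML")
        t2_oracle, pooled_oracle = reml_grid_search(y, v)
        assert fit.tau2 == pytest.approx(t2_oracle, abs=1e-5)
        assert fit.pooled == pytest.approx(pooled_oracle, abs=1e-5)

    def test_dl_matches_statsmodels(self, rng):
        # statsmodels does not truncate the DL moment estimator at zero;
        # compare on draws where it is positive, else check the boundary
        compared = 0
        while compared < 10:
            y, v = random_meta(rng, k=int(rng.integers(3, 12)))
            res = combine_effects(y, v, method_re="dl")
            ours = fit_random_effects(make_estimates(y, np.sqrt(v)), method="DL")
            if res.tau2 <= 0:
                assert ours.tau2 == 0.0
                continue
            assert ours.tau2 == pytest.approx(res.tau2, abs=1e-10)
            sm = res.summary_frame().loc["random effect"]
            assert ours.pooled == pytest.approx(sm["eff"], abs=1e-10)
            assert ours.se_pooled == pytest.approx(sm["sd_eff"], abs=1e-10)
            compared += 1

    def test_dl_and_reml_agree_when_q_below_df(self):
        # homogeneous data: both estimators hit the tau2 = 0 boundary
        ests = make_estimates([0.10, 0.101, 0.099, 0.1005], [0.05] * 4)
        dl = fit_random_effects(ests, method="DL")
        reml = fit_random_effects(ests, method="REML")
        assert dl.Q <= len(ests) - 1
        assert dl.tau2 == reml.tau2 == 0.0
        assert dl.pooled == pytest.approx(reml.pooled, abs=1e-12)

    def test_permutation_invariance(self, rng):
        y, v = random_meta(rng, k=9)
        ests = make_estimates(y, np.sqrt(v))
        perm = [ests[i] for i in rng.permutation(len(ests))]
        a, b = fit_random_effects(ests), fit_random_effects(perm)
        assert a.pooled == pytest.approx(b.pooled, abs=1e-10)
        assert a.tau2 == pytest.approx(b.tau2, abs=1e-10)
        assert a.Q == pytest.approx(b.Q, abs=1e-10)

    def test_scaling_equivariance(self, rng):
        y, v = random_meta(rng, k=8)
        c = 3.7
        base = fit_random_effects(make_estimates(y, np.sqrt(v)))
        scaled = fit_random_effects(make_estimates(c * y, c * np.sqrt(v)))
        assert scaled.pooled == pytest.approx(c * base.pooled, rel=1e-6)
        assert scaled.se_pooled == pytest.approx(c * base.se_pooled, rel=1e-6)
        assert scaled.z == pytest.approx(base.z, rel=1e-6)
        assert scaled.I2 == pytest.approx(base.I2, rel=1e-6)
        assert scaled.Q_p == pytest.approx(base.Q_p, rel=1e-6)

    def test_too_few_estimates_rejected(self):
        with pytest.raises(MetaAnalysisError, match="at least 2"):
            fit_random_effects(make_estimates([0.1], [0.05]))

    def test_zero_variance_estimate_rejected(self):
        ests = make_estimates([0.1, 0.2, 0.0], [0.05, 0.05, 0.0])
        with pytest.raises(MetaAnalysisError, match="zero-variance"):
            fit_random_effects(ests)


class TestHeterogeneity:
    def test_hand_computed_q(self):
        # d = 0, 0.1, 0.2 with se = 0.05: FE mean 0.1, Q = 2 x 0.01/0.0025
        y = np.array([0.0, 0.1, 0.2])
        v = np.full(3, 0.05**2)
        Q, Q_p, I2, I2_q = heterogeneity(y, v, tau2=0.0)
        assert Q == pytest.approx(8.0)
        assert I2 == pytest.approx(0.0)  # tau2-based definition at tau2=0
        assert I2_q == pytest.approx(100.0 * 6 / 8)

    def test_q_expectation_under_homogeneity(self, rng):
        # with tau = 0, E[Q] = k - 1
        k, reps = 6, 2000
        se = rng.uniform(0.02, 0.1, size=(reps, k))
        y = rng.normal(0.0, se)
        qs = []
        for r in range(reps):
            Q, *_ = heterogeneity(y[r], se[r] ** 2, 0.0)
            qs.append(Q)
        assert np.mean(qs) == pytest.approx(k - 1, abs=0.2)


class TestLeaveOneOut:
    def test_identical_estimates_no_flags(self):
        ests = make_estimates([0.1] * 5, [0.05] * 5)
        results = leave_one_out(ests)
        assert len(results) == 5
        assert not any(r.outside_full_ci or r.significance_changed for r in results)
        pooled = {round(r.result.pooled, 12) for r in results}
        assert pooled == {0.1}

    def test_outlier_omission_flips_significance(self):
        # four consistent positive estimates and one opposing outlier: the
        # full model is non-significant, dropping the outlier makes it so
        ests = make_estimates([0.1, 0.1, 0.1, 0.1, -0.1], [0.02] * 5)
        full = fit_random_effects(ests)
        assert full.p >= 0.05
        results = leave_one_out(ests)
        flagged = [r.omitted_id for r in results if r.significance_changed]
        assert flagged == ["e4"]
        # direct refit confirms the flag
        refit = fit_random_effects(ests[:4])
        assert refit.p < 0.05

    def test_influence_flags_agree_with_direct_refits(self):
        ests = make_estimates(
            [0.02, 0.01, -0.01, 0.0, 0.9],
            [0.05, 0.05, 0.05, 0.05, 0.001],
        )
        full = fit_random_effects(ests)
        for r in leave_one_out(ests):
            refit = fit_random_effects(
                [e for e in ests if e.estimate_id != r.omitted_id]
            )
            assert r.result.pooled == pytest.approx(refit.pooled, abs=1e-10)
            assert r.outside_full_ci == (
                not full.ci_low <= refit.pooled <= full.ci_high
            )

    def test_output_length_equals_k(self, rng):
        y, v = random_meta(rng, k=7)
        assert len(leave_one_out(make_estimates(y, np.sqrt(v)))) == 7

    def test_needs_three_estimates(self):
        with pytest.raises(MetaAnalysisError):
            leave_one_out(make_estimates([0.1, 0.2], [0.05, 0.05]))
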