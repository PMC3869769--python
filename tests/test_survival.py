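"""Cox, Kaplan-Meier, log-rank and martingale-residual unit tests."""

import numpy as np
import pandas as pd
import pytest

from melres import (
    ConvergenceError,
    CoxPH,
    DegenerateCovariateError,
    SurvivalData,
    fit_cox,
    km_estimate,
    logrank_test,
    martingale_residuals,
)

from _oracles import grid_cox_mle, hand_km, hand_logrank_2group


class TestSurvivalData:
    def test_rejects_nonpositive_times(self):
        with pytest.raises(ValueError):
            SurvivalData(np.array([1.0, 0.0]), np.array([1, 0]))

    def test_rejects_non_binary_events(self):
        with pytest.raises(ValueError):
            SurvivalData(np.array([1.0, 2.0]), np.array([1, 2]))


class TestCoxFit:
    def test_matches_brute_force_grid_oracle(self):
        """Coefficient agrees with grid maximisation of the hand-written
        partial likelihood on a tiny all-event instance."""
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        fit = fit_cox(x[:, None], (time, event))
        oracle = grid_cox_mle(time, event, x)
        assert abs(fit.coef_[0] - oracle) < 1e-3

    def test_matches_grid_oracle_with_ties_and_censoring(self):
        time = np.array([2.0, 2.0, 3.0, 5.0, 5.0, 7.0, 8.0, 8.0])
        event = np.array([1, 1, 0, 1, 1, 1, 0, 1])
        x = np.array([0.5, -1.0, 0.0, 1.5, -0.5, 1.0, 0.0, -1.5])
        fit = fit_cox(x[:, None], (time, event))
        oracle = grid_cox_mle(time, event, x)
        assert abs(fit.coef_[0] - oracle) < 1e-3

    def test_agrees_with_lifelines_on_random_instances(self):
        """Independent reference agreement (coefficients to 1e-6) on 50
        random multivariable instances with censoring."""
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = int(rng.integers(20, 45))
            p = int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            beta = rng.uniform(-0.8, 0.8, p)
            t = rng.exponential(1.0 / (0.05 * np.exp(X @ beta)))
            e = (rng.random(n) < 0.75).astype(int)
            if e.sum() < p + 2:
                e[: p + 2] = 1
            fit = fit_cox(X, (t, e))
            df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
            df["T"], df["E"] = t, e
            cph = lifelines.CoxPHFitter()
            # tighten the reference's own stopping rule so the 1e-6
            # comparison measures agreement, not its convergence slack
            cph.fit(df, "T", "E", fit_options={"precision": 1e-13})
            np.testing.assert_allclose(fit.coef_, cph.params_.to_numpy(),
                                       atol=1e-6)
            np.testing.assert_allclose(fit.se_, cph.standard_errors_.to_numpy(),
                                       atol=1e-6)

    def test_constant_column_raises_named_error(self):
        X = np.column_stack([np.ones(5), np.arange(5.0)])
        with pytest.raises(DegenerateCovariateError, match="x0"):
            fit_cox(X, (np.arange(1.0, 6.0), np.ones(5, int)))

    def test_perfect_separation_raises_convergence_error(self):
        # covariate perfectly orders the event times: monotone likelihood
        t = np.arange(1.0, 9.0)
        e = np.ones(8, int)
        x = -t
        with pytest.raises(ConvergenceError):
            fit_cox(x[:, None], (t, e))

    def test_coefficients_invariant_to_centering(self, rng):
        n = 80
        X = rng.standard_normal((n, 2))
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.7).astype(int)
        f1 = fit_cox(X, (t, e))
        f2 = fit_cox(X + np.array([5.0, -3.0]), (t, e))
        np.testing.assert_allclose(f1.coef_, f2.coef_, atol=1e-8)
        lp_diff = f2.linear_predictor_ - f1.linear_predictor_
        np.testing.assert_allclose(lp_diff, lp_diff[0], atol=1e-8)

    def test_hazard_ratio_and_ci_shapes(self, rng):
        n = 60
        X = rng.standard_normal((n, 2))
        t = rng.exponential(10, n)
        e = np.ones(n, int)
        fit = fit_cox(X, (t, e))
        np.testing.assert_allclose(fit.hazard_ratios_, np.exp(fit.coef_))
        np.testing.assert_allclose(
            fit.hr_confint_[:, 0], np.exp(fit.coef_ - 1.959964 * fit.se_),
            rtol=1e-6)
        assert fit.loglik_ >= fit.loglik_null_

    def test_breslow_option_differs_only_with_ties(self, rng):
        n = 40
        x = rng.standard_normal(n)
        t = np.round(rng.exponential(10, n)) + 1.0  # force ties
        e = np.ones(n, int)
        fe = fit_cox(x[:, None], (t, e), ties="efron")
        fb = fit_cox(x[:, None], (t, e), ties="breslow")
        assert abs(fe.coef_[0] - fb.coef_[0]) > 0
        t2 = rng.exponential(10, n)  # continuous: no ties
        fe2 = fit_cox(x[:, None], (t2, e), ties="efron")
        fb2 = fit_cox(x[:, None], (t2, e), ties="breslow")
        np.testing.assert_allclose(fe2.coef_, fb2.coef_, atol=1e-9)


class TestKaplanMeier:
    def test_hand_product_limit_values(self):
        km = km_estimate((np.array([1.0, 2, 3, 4, 5]), np.array([1, 1, 0, 1, 0])))
        np.testing.assert_allclose(km.event_times, [1.0, 2.0, 4.0])
        np.testing.assert_allclose(km.survival, [0.8, 0.6, 0.3])
        assert km.survival_at(3.5) == pytest.approx(0.6)

    def test_no_censoring_reduces_to_empirical_cdf(self, rng):
        t = rng.exponential(5, 100)
        km = km_estimate((t, np.ones(100, int)))
        grid = np.quantile(t, [0.1, 0.4, 0.8])
        np.testing.assert_allclose(km.survival_at(grid), 1 - (t[:, None] <= grid).mean(0))

    def test_all_censored_gives_flat_curve(self):
        km = km_estimate((np.array([1.0, 2.0, 3.0]), np.zeros(3, int)))
        assert len(km.event_times) == 0
        assert np.isnan(km.median)
        assert km.survival_at(10.0) == 1.0

    def test_matches_hand_oracle_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 40))
            t = np.round(rng.exponential(10, n), 1) + 0.1
            e = (rng.random(n) < 0.7).astype(int)
            if e.sum() == 0:
                e[0] = 1
            km = km_estimate((t, e))
            ot, os_ = hand_km(t, e)
            np.testing.assert_allclose(km.event_times, ot)
            np.testing.assert_allclose(km.survival, os_, atol=1e-12)

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 30
            t = r.exponential(10, n)
            e = (r.random(n) < 0.6).astype(int)
            if e.sum() == 0:
                e[0] = 1
            km = km_estimate((t, e))
            kmf = lifelines.KaplanMeierFitter().fit(t, e)
            ours = km.survival_at(km.event_times)
            theirs = kmf.survival_function_at_times(km.event_times).to_numpy()
            np.testing.assert_allclose(ours, theirs, atol=1e-6)


class TestLogRank:
    def test_identical_groups_give_zero(self):
        t = np.array([1.0, 2, 3, 4])
        e = np.array([1, 0, 1, 1])
        res = logrank_test((np.r_[t, t], np.r_[e, e]),
                           np.r_[np.zeros(4), np.ones(4)])
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_hand_hypergeometric_8_subject_instance(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        event = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        group = np.array([1, 0, 1, 1, 0, 0, 1, 0])
        res = logrank_test((time, event), group)
        assert res.df == 1
        assert res.chi_square == pytest.approx(
            hand_logrank_2group(time, event, group), abs=1e-10)

    def test_three_identical_groups_df(self):
        t = np.array([1.0, 2, 3])
        e = np.array([1, 1, 0])
        res = logrank_test((np.r_[t, t, t], np.r_[e, e, e]),
                           np.repeat([0, 1, 2], 3))
        assert res.df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test((np.array([1.0, 2.0]), np.array([1, 1])), np.zeros(2))

    def test_two_group_equals_cox_score_test(self, rng):
        """Without ties, the 2-group log-rank statistic equals the squared
        score test of a binary-covariate Cox model at beta = 0."""
        n = 50
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(10 / (1 + x), n)
        e = (rng.random(n) < 0.8).astype(int)
        if e.sum() == 0:
            e[0] = 1
        res = logrank_test((t, e), x)
        model = CoxPH()
        surv = SurvivalData(t, e)
        S = model._prepare(x[:, None], surv)
        _, grad, info = model._loglik_grad_info(np.zeros(1), S)
        score_chi2 = grad[0] ** 2 / info[0, 0]
        assert res.chi_square == pytest.approx(score_chi2, abs=1e-6)


class TestMartingaleResiduals:
    def test_sum_zero_and_bounded(self, rng):
        n = 100
        X = rng.standard_normal((n, 2))
        t = rng.exponential(10, n)  # continuous: no ties
        e = (rng.random(n) < 0.7).astype(int)
        fit = fit_cox(X, (t, e))
        res = martingale_residuals(fit)
        assert abs(res.sum()) < 1e-8
        assert np.all(res <= 1.0)

    def test_null_model_event_at_largest_time_hand_breslow(self):
        """In the covariate-free model, the residual of the last event equals
        1 - total Nelson-Aalen hazard; verified by hand on 4 subjects."""
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        fit = fit_cox(np.empty((4, 0)), (t, e))
        # Nelson-Aalen: 1/4 + 1/2 + 1/1
        H_total = 1 / 4 + 1 / 2 + 1 / 1
        res = martingale_residuals(fit)
        assert res[3] == pytest.approx(1.0 - H_total, abs=1e-6)
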