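"""Likelihood exactness, MLE correctness and recovery, LRT, correlation."""

import numpy as np
import pytest
from scipy import optimize

from bivpois.distributions import (RatePair, TruncationBounds, joint_pmf,
                                   log_joint_pmf, log_trunc_joint_pmf)
from bivpois.regression import (BivariateCountData, ModelSpec,
                                correlation_estimate, correlation_from_means,
                                fit, fit_intercept_only, loglik_truncated,
                                loglik_untruncated, lr_test, _trunc_score)
from bivpois.synthetic import generate, scenario_suite


def _intercept_data(y1, y2):
    y1 = np.asarray(y1)
    return BivariateCountData(y1, np.asarray(y2), np.ones((len(y1), 1)), ["const"])


class TestLoglik:
    def test_single_row_zero_pair(self):
        data = _intercept_data([0], [0])
        assert loglik_untruncated([0.0], [0.0], data) == pytest.approx(-1.0)

    def test_single_row_one_one(self):
        data = _intercept_data([1], [1])
        assert loglik_untruncated([0.0], [0.0], data) == pytest.approx(-2.0)

    def test_matches_sum_of_log_joint_pmf(self, well_specified_data):
        data, _ = well_specified_data
        b1 = np.array([0.4, -0.2])
        b2 = np.array([-0.1, 0.3])
        ll = loglik_untruncated(b1, b2, data)
        lam1 = np.exp(data.X @ b1)
        lam2 = np.exp(data.X @ b2)
        oracle = sum(
            log_joint_pmf(y1, y2, RatePair(l1, l2))
            for y1, y2, l1, l2 in zip(data.y1, data.y2, lam1, lam2)
        )
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_truncated_matches_sum_of_log_trunc_pmf(self, truncated_data):
        data, truth = truncated_data
        b = TruncationBounds(**truth["bounds"])
        b1 = np.array([0.9, 0.1])
        b2 = np.array([-0.3, 0.1])
        ll = loglik_truncated(b1, b2, data, b)
        lam1 = np.exp(data.X @ b1)
        lam2 = np.exp(data.X @ b2)
        oracle = sum(
            log_trunc_joint_pmf(y1, y2, RatePair(l1, l2), b)
            for y1, y2, l1, l2 in zip(data.y1, data.y2, lam1, lam2)
        )
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_truncated_equals_untruncated_for_wide_bounds(self, well_specified_data):
        data, _ = well_specified_data
        b1 = np.array([0.5, -0.3])
        b2 = np.array([-0.2, 0.4])
        wide = TruncationBounds(60, 60)
        assert loglik_truncated(b1, b2, data, wide) == pytest.approx(
            loglik_untruncated(b1, b2, data), abs=1e-8)

    def test_overflow_guard(self):
        data = _intercept_data([1, 2], [0, 1])
        with pytest.raises(FloatingPointError):
            loglik_untruncated([800.0], [0.0], data)

    def test_counts_beyond_bounds_rejected(self):
        data = _intercept_data([3, 1], [0, 1])
        with pytest.raises(ValueError):
            loglik_truncated([0.0], [0.0], data, TruncationBounds(2, 5))

    def test_zero_pair_rows_allowed_positive_y2_at_zero_y1_rejected(self):
        _intercept_data([0, 1], [0, 1])  # fine
        with pytest.raises(ValueError):
            _intercept_data([0, 1], [2, 1])


class TestFit:
    def test_intercept_only_closed_forms(self, rng):
        y1 = rng.poisson(2.0, size=400)
        y2 = rng.poisson(0.5 * y1)
        data = _intercept_data(y1, y2)
        res = fit(data)
        assert res.beta1[0] == pytest.approx(np.log(y1.mean()), abs=1e-8)
        assert res.beta2[0] == pytest.approx(np.log(y2.sum() / y1.sum()), abs=1e-8)

    def test_untruncated_recovery_within_3se(self, suite):
        data, truth = generate(suite["well_specified"], n=5000, seed=7)
        res = fit(data)
        truth_vec = np.array(truth["beta1"] + truth["beta2"])
        assert res.converged
        assert np.all(np.abs(res.params - truth_vec) < 3 * res.se)

    def test_truncated_recovery_and_contrast(self, suite):
        data, truth = generate(suite["truncated_tight"], n=5000, seed=8)
        spec = ModelSpec("right_truncated", TruncationBounds(**truth["bounds"]))
        res = fit(data, spec)
        truth_vec = np.array(truth["beta1"] + truth["beta2"])
        assert res.converged
        assert np.all(np.abs(res.params - truth_vec) < 3 * res.se)
        naive = fit(data)  # untruncated model on truncated data is biased
        assert np.max(np.abs(naive.params - res.params)) > 0.05

    def test_truncated_fit_converges_to_untruncated_for_wide_bounds(self, suite):
        data, _ = generate(suite["well_specified"], n=2000, seed=9)
        wide = TruncationBounds(int(10 * data.y1.max()), int(10 * data.y2.max()))
        res_t = fit(data, ModelSpec("right_truncated", wide), compute_se=False)
        res_u = fit(data, compute_se=False)
        assert np.max(np.abs(res_t.params - res_u.params)) < 1e-4

    def test_joint_numeric_fit_agrees_with_two_stage(self, well_specified_data):
        """The separable likelihood's joint optimum equals the two-GLM fit."""
        data, _ = well_specified_data
        res = fit(data, compute_se=False)

        def nll(p):
            return -loglik_untruncated(p[:2], p[2:], data)

        direct = optimize.minimize(nll, res.params + 0.05, method="BFGS",
                                   options={"gtol": 1e-10})
        assert np.max(np.abs(direct.x - res.params)) < 1e-6

    def test_score_vanishes_at_truncated_optimum(self, truncated_data):
        data, truth = truncated_data
        b = TruncationBounds(**truth["bounds"])
        res = fit(data, ModelSpec("right_truncated", b), compute_se=False)
        g = _trunc_score(res.params, data, b)
        assert np.max(np.abs(g)) / data.n < 1e-5

    def test_vcov_diagonal_positive_and_se_consistent(self, well_specified_data):
        data, _ = well_specified_data
        res = fit(data)
        assert np.all(np.diag(res.vcov) > 0)
        assert np.allclose(res.se, np.sqrt(np.diag(res.vcov)))
        assert np.allclose(res.vcov, res.vcov.T)

    def test_default_bounds_recorded(self, truncated_data):
        data, _ = truncated_data
        res = fit(data, ModelSpec("right_truncated"), compute_se=False)
        assert res.spec.bounds.k1 == int(data.y1.max())
        assert res.spec.bounds.k2 == int(data.y2.max())

    @pytest.mark.parametrize("scenario", ["well_specified", "truncated_tight"])
    def test_rmse_decreases_with_n(self, suite, scenario):
        cfg = suite[scenario]
        spec = (ModelSpec("right_truncated", cfg.bounds)
                if cfg.bounds else ModelSpec())
        truth_vec = np.array(cfg.beta1 + cfg.beta2)
        rmse = {}
        for n in (500, 8000):
            errs = []
            for seed in (1, 2, 3):
                data, _ = generate(cfg, n=n, seed=seed)
                res = fit(data, spec, compute_se=False)
                errs.append(np.mean((res.params - truth_vec) ** 2))
            rmse[n] = np.sqrt(np.mean(errs))
        assert rmse[8000] < rmse[500]

    def test_rank_deficiency_rejected(self, rng):
        y1 = rng.poisson(2.0, size=100)
        y2 = rng.poisson(0.5 * y1)
        X = np.column_stack([np.ones(100), np.ones(100)])
        data = BivariateCountData(y1, y2, X, ["const", "dup"])
        with pytest.raises(ValueError):
            fit(data)


class TestLRT:
    def test_identical_models_give_zero(self, well_specified_data):
        data, _ = well_specified_data
        res = fit(data, compute_se=False)
        lr = lr_test(res, res)
        assert lr.statistic == 0.0
        assert lr.p_value == 1.0

    def test_statistic_matches_brute_force(self, well_specified_data):
        data, _ = well_specified_data
        full = fit(data, compute_se=False)
        reduced = fit_intercept_only(data, compute_se=False)
        lr = lr_test(full, reduced)
        assert lr.df == 2
        assert lr.statistic == pytest.approx(
            -2 * (reduced.loglik - full.loglik), abs=1e-9)

    def test_variant_mismatch_rejected(self, truncated_data):
        data, truth = truncated_data
        b = TruncationBounds(**truth["bounds"])
        full = fit(data, ModelSpec("right_truncated", b), compute_se=False)
        reduced = fit_intercept_only(data, compute_se=False)
        with pytest.raises(ValueError):
            lr_test(full, reduced)


class TestCorrelation:
    def test_health_survey_worked_value(self):
        est = correlation_from_means(2.642716, 0.769176, 5568)
        assert est.r == pytest.approx(0.4748, abs=5e-4)
        assert 0 < est.se_r < 1e-5

    def test_zero_y2_gives_zero(self):
        assert correlation_from_means(2.0, 0.0, 100).r == 0.0

    def test_equal_means_give_sqrt_half(self):
        assert correlation_from_means(1.5, 1.5, 100).r == pytest.approx(
            np.sqrt(0.5), rel=1e-12)

    def test_from_data_matches_means(self, well_specified_data):
        data, _ = well_specified_data
        est = correlation_estimate(data)
        ref = correlation_from_means(data.y1.mean(), data.y2.mean(), data.n)
        assert est.r == ref.r

    def test_all_zero_y1_rejected(self):
        data = _intercept_data([0, 0, 0], [0, 0, 0])
        with pytest.raises(ValueError):
            correlation_estimate(data)
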