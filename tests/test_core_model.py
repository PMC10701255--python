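"""Unit tests for the pseudo-likelihood logistic fit and its covariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit

import caseboot as cb
from caseboot.core_model import PseudoDataset
from caseboot.errors import (
    DegenerateDataError,
    DataIntegrityError,
    NonConvergenceError,
    RankDeficiencyError,
)

from conftest import pseudo_from_2x2


def _random_logistic_dataset(rng, n, beta):
    """Simulated rows with D ~ Bernoulli(expit(X beta)); resampled until
    both D values are present."""
    p = len(beta) - 1
    while True:
        X = np.column_stack([np.ones(n), rng.standard_normal((n, p))])
        d = (rng.random(n) < expit(X @ np.asarray(beta))).astype(float)
        if 0 < d.sum() < n:
            return PseudoDataset(X=X, d=d)


class TestFitLogistic:
    def test_two_by_two_matches_closed_form(self, two_by_two):
        """On saturated 2x2 data the fit reproduces the empirical log odds
        ratio and the Woolf standard error."""
        fit = cb.fit_logistic(two_by_two)
        assert fit.converged
        assert fit.beta[1] == pytest.approx(math.log(4.0), abs=1e-8)
        # intercept = log odds of D=1 among the unexposed
        assert fit.beta[0] == pytest.approx(math.log(5 / 40), abs=1e-8)
        woolf = math.sqrt(1 / 10 + 1 / 5 + 1 / 20 + 1 / 40)
        assert math.sqrt(fit.model_cov[1, 1]) == pytest.approx(woolf, rel=1e-6)

    def test_balanced_symmetric_data_gives_zero_slope(self):
        ds = pseudo_from_2x2(10, 10, 25, 25)
        fit = cb.fit_logistic(ds)
        assert fit.beta[1] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_score_vanishes_at_optimum(self, seed):
        """First-order condition: converged fits have score max-norm < tol."""
        rng = np.random.default_rng(seed)
        ds = _random_logistic_dataset(rng, 300, [-0.5, 0.8, -0.3])
        fit = cb.fit_logistic(ds, tol=1e-8)
        mu = expit(ds.X @ fit.beta)
        assert np.abs(ds.X.T @ (ds.d - mu)).max() < 1e-8
        assert fit.n_iter <= 100

    def test_covariances_are_symmetric_psd(self, two_by_two):
        fit = cb.fit_logistic(two_by_two)
        for cov in (fit.model_cov, fit.robust_cov):
            assert np.allclose(cov, cov.T)
            assert np.linalg.eigvalsh(cov).min() > -1e-12

    def test_matches_independent_glm_fit(self):
        """Cross-check coefficients, model and robust covariances against
        statsmodels GLM (an implementation this package does not use)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        ds = _random_logistic_dataset(rng, 400, [-0.2, 0.6, -0.9, 0.3])
        fit = cb.fit_logistic(ds)
        ref = sm.GLM(ds.d, ds.X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.beta, ref.params, atol=1e-6)
        np.testing.assert_allclose(
            fit.model_cov, ref.cov_params(), rtol=1e-5, atol=1e-8
        )
        robust = sm.GLM(ds.d, ds.X, family=sm.families.Binomial()).fit(
            cov_type="HC0"
        )
        np.testing.assert_allclose(
            fit.robust_cov, robust.cov_params(), rtol=1e-5, atol=1e-8
        )

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(40), np.arange(40.0), 2 * np.arange(40.0)])
        d = np.concatenate([np.ones(20), np.zeros(20)])
        with pytest.raises(RankDeficiencyError):
            cb.fit_logistic(PseudoDataset(X=X, d=d))

    def test_single_valued_membership_raises(self):
        with pytest.raises(DegenerateDataError):
            PseudoDataset(X=np.ones((5, 1)), d=np.ones(5))

    def test_separation_raises_nonconvergence_with_state(self):
        ds = pseudo_from_2x2(12, 0, 0, 15)  # z perfectly predicts D
        with pytest.raises(NonConvergenceError) as err:
            cb.fit_logistic(ds)
        assert err.value.beta is not None
        assert err.value.n_iter is not None

    def test_id_duplication_rules_enforced(self):
        X = np.column_stack([np.ones(4), [1.0, 0.0, 1.0, 0.0]])
        d = np.array([1.0, 1.0, 0.0, 0.0])
        # one id in both blocks is fine
        PseudoDataset(X=X, d=d, ids=np.array(["a", "b", "a", "c"]))
        with pytest.raises(DataIntegrityError):
            PseudoDataset(X=X, d=d, ids=np.array(["a", "a", "b", "c"]))
        with pytest.raises(DataIntegrityError):
            PseudoDataset(X=X, d=d, ids=np.array(["a", "a", "a", "b"]))


class TestRobustCovariance:
    def test_equals_model_covariance_on_saturated_2x2(self, two_by_two):
        """With a saturated model the sandwich collapses onto the inverse
        information."""
        fit = cb.fit_logistic(two_by_two)
        cov = cb.robust_covariance(two_by_two, fit)
        np.testing.assert_allclose(cov, fit.model_cov, rtol=1e-6)

    def test_bread_and_meat_match_finite_differences(self):
        """A = observed information and B = sum of score outer products,
        both checked against numerical derivatives of the log-likelihood
        (complex-step gradients, which are cancellation-free)."""
        rng = np.random.default_rng(8)
        ds = _random_logistic_dataset(rng, 40, [0.2, -0.5, 0.7])
        fit = cb.fit_logistic(ds)
        beta, X, d = fit.beta, ds.X, ds.d
        p = beta.size

        def loglik(b, rows=slice(None)):
            # complex-safe Bernoulli log-likelihood
            eta = X[rows] @ b
            return d[rows] @ eta - np.sum(np.log(1.0 + np.exp(eta)))

        def grad(b, rows=slice(None)):
            h = 1e-10
            g = np.empty(p)
            for j in range(p):
                e = np.zeros(p, dtype=complex)
                e[j] = 1j * h
                g[j] = loglik(b + e, rows).imag / h
            return g

        h = 1e-5
        hess = np.empty((p, p))
        for j in range(p):
            e = np.zeros(p)
            e[j] = h
            hess[j] = (grad(beta + e) - grad(beta - e)) / (2 * h)
        mu = expit(X @ beta)
        a = X.T @ (X * (mu * (1 - mu))[:, None])
        np.testing.assert_allclose(a, -hess, atol=1e-6)

        b_mat = sum(np.outer(g, g) for g in (grad(beta, [i]) for i in range(ds.n)))
        b_direct = X.T @ (X * ((d - mu) ** 2)[:, None])
        np.testing.assert_allclose(b_direct, b_mat, atol=1e-6)
        # and the sandwich assembled from A and B
        np.testing.assert_allclose(
            fit.robust_cov,
            np.linalg.inv(a) @ b_direct @ np.linalg.inv(a),
            atol=1e-10,
        )

    def test_asymptotic_equivalence_without_duplication(self):
        """Robust and model SEs agree on large unduplicated case-control
        data (ratio within 2% of 1)."""
        rng = np.random.default_rng(4)
        n = 10_000
        z = (rng.random(n) < 0.3).astype(float)
        d = (rng.random(n) < expit(-1.0 + 0.8 * z)).astype(float)
        ds = PseudoDataset(X=np.column_stack([np.ones(n), z]), d=d)
        fit = cb.fit_logistic(ds)
        ratio = math.sqrt(fit.robust_cov[1, 1] / fit.model_cov[1, 1])
        assert abs(ratio - 1.0) < 0.02

    def test_overestimation_of_true_sampling_se_under_duplication(
        self, default_params
    ):
        """With duplicated participants the sandwich SE overestimates the
        actual sampling SD of the slope estimator (while staying close to
        the model SE, with which it is asymptotically equivalent)."""
        params = default_params.with_(n_cohort=1000)
        slopes, robust_ses, ratios = [], [], []
        for seed in range(400):
            cohort = cb.generate_cohort(params, rng_seed=100 + seed)
            sample = cb.draw_case_cohort_sample(cohort, 0.2, rng_seed=5000 + seed)
            fit = cb.fit_logistic(sample.pseudo)
            slopes.append(fit.beta[1])
            robust_ses.append(math.sqrt(fit.robust_cov[1, 1]))
            ratios.append(math.sqrt(fit.robust_cov[1, 1] / fit.model_cov[1, 1]))
        assert np.mean(robust_ses) > np.std(slopes, ddof=1)
        assert abs(np.mean(ratios) - 1.0) < 0.05

    def test_requires_converged_fit(self, two_by_two):
        fit = cb.fit_logistic(two_by_two)
        stale = cb.FitResult(
            beta=fit.beta,
            model_cov=fit.model_cov,
            robust_cov=fit.robust_cov,
            loglik=fit.loglik,
            converged=False,
            n_iter=0,
        )
        with pytest.raises(NonConvergenceError):
            cb.robust_covariance(two_by_two, stale)


class TestWaldInterval:
    def test_standard_normal_quantile(self):
        lo, hi = cb.wald_interval(0.0, 1.0, 0.95)
        assert lo == pytest.approx(-1.959964, abs=1e-6)
        assert hi == pytest.approx(1.959964, abs=1e-6)

    def test_worked_arithmetic(self):
        lo, hi = cb.wald_interval(0.96, 0.193, 0.95)
        assert lo == pytest.approx(0.5817, abs=1e-4)
        assert hi == pytest.approx(1.3383, abs=1e-4)

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            cb.wald_interval(0.0, 0.0, 0.95)
        with pytest.raises(ValueError):
            cb.wald_interval(0.0, -1.0, 0.95)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        est=st.floats(-5, 5),
        se=st.floats(0.01, 10),
        lo_level=st.floats(0.05, 0.90),
        hi_level=st.floats(0.905, 0.999),
    )
    def test_width_increases_with_level_and_brackets_estimate(
        self, est, se, lo_level, hi_level
    ):
        a = cb.wald_interval(est, se, lo_level)
        b = cb.wald_interval(est, se, hi_level)
        assert a[0] < est < a[1]
        assert (b[1] - b[0]) > (a[1] - a[0])
        # symmetric around the estimate
        assert (est - a[0]) == pytest.approx(a[1] - est, rel=1e-9, abs=1e-12)


class TestRiskRatioReport:
    def test_excludes_intercept_and_exponentiates(self, two_by_two):
        fit = cb.fit_logistic(two_by_two)
        rep = cb.risk_ratio_report(fit, "model")
        assert list(rep.index) == ["z"]
        assert rep.loc["z", "rr"] == pytest.approx(4.0, rel=1e-6)
        lo, hi = cb.wald_interval(fit.beta[1], rep.loc["z", "se"], 0.95)
        assert rep.loc["z", "rr_lower"] == pytest.approx(math.exp(lo))
        assert rep.loc["z", "rr_upper"] == pytest.approx(math.exp(hi))
        assert rep.loc["z", "rr_lower"] < rep.loc["z", "rr"] < rep.loc["z", "rr_upper"]

    def test_paper_scale_exponentiation(self):
        assert math.exp(0.96) == pytest.approx(2.6117, abs=1e-4)

    def test_zero_slope_gives_unit_rr_with_log_symmetric_ci(self):
        ds = pseudo_from_2x2(10, 10, 25, 25)
        fit = cb.fit_logistic(ds)
        rep = cb.risk_ratio_report(fit, "model")
        assert rep.loc["z", "rr"] == pytest.approx(1.0, abs=1e-8)
        assert rep.loc["z", "rr_lower"] * rep.loc["z", "rr_upper"] == pytest.approx(
            1.0, abs=1e-6
        )

    def test_supplied_se_path(self, two_by_two):
        fit = cb.fit_logistic(two_by_two)
        rep = cb.risk_ratio_report(
            fit, "supplied", supplied_se=np.array([0.1, 0.193])
        )
        assert rep.loc["z", "se"] == 0.193
        with pytest.raises(ValueError):
            cb.risk_ratio_report(fit, "supplied")
        with pytest.raises(ValueError):
            cb.risk_ratio_report(fit, "bogus")
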