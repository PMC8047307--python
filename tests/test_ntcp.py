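"""Logistic dose/volume response model: fitting, Wald table, inversion."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from dvhtox import (
    LogisticNTCP,
    SynthConfig,
    covariate_adjustment_check,
    fit_logistic,
    generate_cohort,
    invert_dose,
    metric_values,
    predict_prob,
    response_curve,
    wald_table,
)
from dvhtox.ntcp import NotConvergedError


def grid_search_mle(X, y, span=25.0):
    """Independent likelihood maximiser: coarse grid then Nelder-Mead polish."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    A = np.column_stack([np.ones(X.shape[0]), X])

    def nll(b):
        eta = np.clip(A @ b, -500, 500)
        return -np.sum(y * eta - np.log1p(np.exp(eta)))

    best = None
    for b0 in np.linspace(-span, span, 26):
        for b1 in np.linspace(-span, span, 26):
            v = nll((b0, b1))
            if best is None or v < best[0]:
                best = (v, (b0, b1))
    res = minimize(nll, best[1], method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000})
    return res.x


class TestFit:
    def test_no_signal_symmetric_data(self):
        fit = fit_logistic([0.0, 0.0, 1.0, 1.0], [0, 1, 0, 1])
        assert fit.intercept_ == pytest.approx(0.0, abs=1e-8)
        assert fit.coef_[0] == pytest.approx(0.0, abs=1e-8)
        assert fit.converged_

    def test_alternating_labels_match_grid_oracle(self):
        X = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([0, 1, 0, 1, 0, 1])
        fit = fit_logistic(X, y)
        oracle = grid_search_mle(X, y)
        np.testing.assert_allclose(fit.params_, oracle, atol=1e-4)

    def test_random_small_instances_match_grid_oracle(self):
        rng = np.random.default_rng(6)
        checked = 0
        while checked < 10:
            n = int(rng.integers(8, 31))
            X = rng.normal(size=n)
            y = (rng.random(n) < expit(0.3 + 0.8 * X)).astype(int)
            if y.min() == y.max():
                continue
            fit = fit_logistic(X, y)
            if not fit.converged_ or np.max(np.abs(fit.params_)) > 15:
                continue  # separated draws have no finite MLE to compare
            oracle = grid_search_mle(X, y)
            np.testing.assert_allclose(fit.params_, oracle, atol=1e-4)
            checked += 1

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < expit(-0.5 + X @ [0.8, -0.4])).astype(int)
        fit = fit_logistic(X, y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.params_, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse_, ref.bse, rtol=1e-4)
        assert fit.llf_ == pytest.approx(ref.llf, abs=1e-6)

    def test_score_equations_vanish_at_mle(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=100)
        y = (rng.random(100) < expit(0.2 + 0.5 * X)).astype(int)
        fit = fit_logistic(X, y)
        p = fit.risk(X)
        assert abs(np.sum(y - p)) < 1e-6
        assert abs(np.sum(X * (y - p))) < 1e-6

    def test_separation_flagged_not_raised(self):
        fit = fit_logistic([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0],
                           [0, 0, 0, 0, 1, 1, 1, 1])
        assert fit.separation_
        assert not fit.converged_
        with pytest.raises(NotConvergedError):
            wald_table(fit)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both outcome classes"):
            fit_logistic([1.0, 2.0, 3.0], [1, 1, 1])

    def test_sklearn_estimator_contract(self):
        model = LogisticNTCP(max_iter=60, tol=1e-9)
        assert model.get_params() == {"max_iter": 60, "tol": 1e-9}
        model.set_params(max_iter=50)
        rng = np.random.default_rng(9)
        X = rng.normal(size=50)
        y = (rng.random(50) < expit(X)).astype(int)
        model.fit(X, y)
        proba = model.predict_proba(X[:5])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(model.predict(X[:5])) <= {0, 1}


class TestWaldTable:
    def test_published_coefficient_odds_ratio(self):
        fit = LogisticNTCP.from_coefficients(
            -11.045, [0.138], cov_params=np.diag([1.192**2, 0.016**2]),
            feature_names=["D_1.2cc"],
        )
        table = wald_table(fit)
        assert table.loc["D_1.2cc", "Exp(B)"] == pytest.approx(1.148, abs=5e-4)
        assert table.loc["D_1.2cc", "Wald"] == pytest.approx((0.138 / 0.016) ** 2)
        assert list(table.index) == ["D_1.2cc", "Constant"]

    def test_zero_coefficient(self):
        fit = LogisticNTCP.from_coefficients(
            0.0, [0.0], cov_params=np.eye(2), feature_names=["x"]
        )
        table = wald_table(fit)
        assert table.loc["x", "Exp(B)"] == 1.0
        assert table.loc["x", "Wald"] == 0.0
        assert table.loc["x", "Sig"] == pytest.approx(1.0)

    def test_hand_wald(self):
        fit = LogisticNTCP.from_coefficients(
            0.0, [0.2], cov_params=np.diag([1.0, 0.01]), feature_names=["x"]
        )
        assert wald_table(fit).loc["x", "Wald"] == pytest.approx(4.0)


class TestPredictAndInvert:
    v72 = LogisticNTCP.from_coefficients(-1.891, [0.247], feature_names=["V_72Gy"])
    d12 = LogisticNTCP.from_coefficients(-11.045, [0.138], feature_names=["D_1.2cc"])

    def test_baseline_risk_v72(self):
        assert predict_prob(self.v72, 0.0) == pytest.approx(0.131, abs=5e-4)

    def test_flat_model(self):
        flat = LogisticNTCP.from_coefficients(0.0, [0.0])
        assert predict_prob(flat, 123.0) == 0.5

    def test_fifty_percent_volume(self):
        assert predict_prob(self.v72, 7.66) == pytest.approx(0.500, abs=5e-4)

    def test_td50_and_td5(self):
        assert invert_dose(self.d12, 0.5).value == pytest.approx(80.0, abs=0.05)
        assert invert_dose(self.d12, 0.05).value == pytest.approx(58.7, abs=0.05)

    def test_symmetric_model_inverts_to_zero(self):
        fit = LogisticNTCP.from_coefficients(0.0, [2.0])
        assert invert_dose(fit, 0.5).value == pytest.approx(0.0)

    def test_zero_slope_rejected(self):
        fit = LogisticNTCP.from_coefficients(1.0, [0.0])
        with pytest.raises(ValueError, match="slope"):
            invert_dose(fit, 0.5)

    def test_invert_predict_round_trip(self):
        rng = np.random.default_rng(10)
        X = rng.normal(60, 8, size=300)
        y = (rng.random(300) < expit(-10 + 0.16 * X)).astype(int)
        fit = fit_logistic(X, y)
        for p in (0.05, 0.2, 0.5, 0.9):
            assert predict_prob(fit, invert_dose(fit, p).value) == pytest.approx(
                p, abs=1e-10
            )

    def test_tolerance_points_increase_with_probability(self):
        pts = [invert_dose(self.d12, p).value for p in (0.05, 0.2, 0.5, 0.8)]
        assert np.all(np.diff(pts) > 0)

    def test_delta_method_ci_brackets_estimate(self):
        fit = LogisticNTCP.from_coefficients(
            -11.045, [0.138],
            cov_params=np.array([[1.192**2, -0.0186], [-0.0186, 0.016**2]]),
        )
        pt = fit.tolerance_dose(0.5)
        assert pt.ci_low < pt.value < pt.ci_high


class TestResponseCurve:
    def test_monotone_and_bounded(self):
        fit = LogisticNTCP.from_coefficients(-11.045, [0.138], feature_names=["D_1.2cc"])
        rc = response_curve(fit, np.linspace(30, 110, 100))
        assert np.all(np.diff(rc.probability) > 0)
        assert np.all((rc.probability > 0) & (rc.probability < 1))

    def test_printed_model_crosses_5pct_between_58_and_59(self):
        fit = LogisticNTCP.from_coefficients(-11.045, [0.138])
        assert fit.risk(58.0) < 0.05 < fit.risk(59.0)

    def test_band_shrinks_with_covariance(self):
        cov = np.diag([0.5, 0.001])
        wide = LogisticNTCP.from_coefficients(-5.0, [0.1], cov_params=cov)
        narrow = LogisticNTCP.from_coefficients(-5.0, [0.1], cov_params=cov * 1e-6)
        x = np.linspace(0, 100, 20)
        w = wide.curve(x)
        n = narrow.curve(x)
        assert np.all((n.band_high - n.band_low) <= (w.band_high - w.band_low) + 1e-12)
        assert np.all(n.band_high - n.band_low < 1e-2)


class TestCovariateAdjustment:
    def test_t_stage_removed_under_metric_only_model(self):
        """Injury depends on the metric alone: T-stage p exceeds 0.05 in most
        seeds (it is uniform under the null)."""
        rng = np.random.default_rng(11)
        removed = 0
        n_rep = 20
        for _ in range(n_rep):
            n = 600
            x = rng.normal(65, 8, size=n)
            t = rng.integers(2, 5, size=n).astype(float)  # independent of x
            y = (rng.random(n) < expit(-11.045 + 0.138 * x)).astype(int)
            fit = fit_logistic(np.column_stack([x, t]), y, feature_names=["m", "T"])
            removed += fit.pvalues_[2] > 0.05
        assert removed >= 16  # ~95% expected

    def test_default_cohort_retains_metric(self):
        cohort = generate_cohort(SynthConfig(n_patients=800, seed=23))
        report = covariate_adjustment_check(cohort)
        assert report["metric_p"] < 0.01  # dose metric is the real driver
        assert report["single_fit"].coef_[0] > 0
        assert report["joint_fit"].n_features_in_ == 2
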