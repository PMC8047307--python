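"""Logistic dose/volume response (NTCP) model.

The complication probability for a dosimetric metric X is modelled as

    P(X) = 1 / (1 + exp(-(b0 + b1 * X)))

fitted by maximum likelihood (iteratively reweighted least squares / Newton
scoring).  The fitted model is inverted for tolerance points TD_p — the
metric value at complication probability p, e.g. TD5/5 and TD50/5 — with
delta-method confidence intervals, and evaluated over a grid for response
curves with pointwise bands.

:class:`LogisticNTCP` follows the scikit-learn estimator contract (``fit``,
``predict_proba``, ``get_params``), so it composes with sklearn pipelines;
the module-level functions are thin wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator, ClassifierMixin

from .screening import metric_values

__all__ = [
    "LogisticNTCP",
    "TolerancePoint",
    "ResponseCurve",
    "fit_logistic",
    "wald_table",
    "predict_prob",
    "invert_dose",
    "response_curve",
    "covariate_adjustment_check",
]

Z_95 = 1.959963984540054


@dataclass
class TolerancePoint:
    """Metric value at a given complication probability, with a delta-method CI."""

    probability: float
    value: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass
class ResponseCurve:
    """P(X) over a metric grid with a pointwise 95% band (when a covariance
    matrix is available)."""

    metric: str
    x: np.ndarray
    probability: np.ndarray
    band_low: np.ndarray | None = None
    band_high: np.ndarray | None = None


class NotConvergedError(RuntimeError):
    """The maximum-likelihood fit did not converge."""


class LogisticNTCP(ClassifierMixin, BaseEstimator):
    """Binary logistic regression fitted by IRLS, with NTCP conveniences.

    Parameters
    ----------
    max_iter : int
        Newton-scoring iteration cap.
    tol : float
        Convergence threshold on the max absolute coefficient update.

    Attributes (after ``fit``)
    --------------------------
    params_ : ndarray, shape (k+1,)
        Intercept first, then one coefficient per covariate.
    cov_params_ : ndarray
        Inverse observed information at the optimum.
    bse_, wald_, pvalues_ : ndarray
        Standard errors, Wald statistics (B/SE)^2 and chi-square(1) p-values,
        aligned with ``params_``.
    converged_, separation_ : bool
        Convergence flag; quasi-complete separation is flagged, not raised.
    """

    def __init__(self, max_iter: int = 50, tol: float = 1e-8):
        self.max_iter = max_iter
        self.tol = tol

    # -- fitting ------------------------------------------------------------

    def fit(self, X, y, feature_names=None) -> "LogisticNTCP":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y).astype(float)
        if y.ndim != 1 or y.shape[0] != X.shape[0]:
            raise ValueError("X and y must have matching first dimensions")
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("y must be binary")
        if y.min() == y.max():
            raise ValueError("both outcome classes must be present in y")
        n, k = X.shape
        if n <= k + 1:
            raise ValueError(f"need more observations ({n}) than coefficients ({k + 1})")

        A = np.column_stack([np.ones(n), X])
        b = np.zeros(k + 1)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = np.clip(A @ b, -35.0, 35.0)
            p = expit(eta)
            w = np.maximum(p * (1.0 - p), 1e-12)
            grad = A.T @ (y - p)
            info = A.T @ (A * w[:, None])
            try:
                delta = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError:
                break
            b = b + delta
            if np.max(np.abs(delta)) < self.tol:
                converged = True
                break

        eta = np.clip(A @ b, -35.0, 35.0)
        p = expit(eta)
        self.params_ = b
        self.intercept_ = float(b[0])
        self.coef_ = b[1:].copy()
        self.n_iter_ = it
        self.converged_ = converged
        # quasi-complete separation: likelihood driven to the boundary
        self.separation_ = bool((not converged) and np.max(np.abs(y - p)) < 1e-3)
        w = np.maximum(p * (1.0 - p), 1e-12)
        info = A.T @ (A * w[:, None])
        try:
            self.cov_params_ = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            self.cov_params_ = np.full((k + 1, k + 1), np.nan)
        self.bse_ = np.sqrt(np.diag(self.cov_params_))
        self.wald_ = (b / self.bse_) ** 2
        self.pvalues_ = chi2.sf(self.wald_, df=1)
        with np.errstate(divide="ignore"):
            self.llf_ = float(np.sum(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = k
        self.feature_names_ = (
            list(feature_names) if feature_names is not None
            else [f"x{i}" for i in range(k)]
        )
        return self

    @classmethod
    def from_coefficients(cls, intercept: float, coefs, cov_params=None,
                          feature_names=None) -> "LogisticNTCP":
        """Build a fitted model from published coefficients (no data needed)."""
        model = cls()
        coefs = np.atleast_1d(np.asarray(coefs, dtype=float))
        model.params_ = np.concatenate([[intercept], coefs])
        model.intercept_ = float(intercept)
        model.coef_ = coefs.copy()
        model.cov_params_ = None if cov_params is None else np.asarray(cov_params, float)
        if model.cov_params_ is not None:
            model.bse_ = np.sqrt(np.diag(model.cov_params_))
            model.wald_ = (model.params_ / model.bse_) ** 2
            model.pvalues_ = chi2.sf(model.wald_, df=1)
        model.converged_ = True
        model.separation_ = False
        model.n_iter_ = 0
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = coefs.size
        model.feature_names_ = (
            list(feature_names) if feature_names is not None
            else [f"x{i}" for i in range(coefs.size)]
        )
        return model

    # -- prediction ---------------------------------------------------------

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        scalar = X.ndim == 0
        if X.ndim <= 1 and self.n_features_in_ == 1:
            X = np.atleast_1d(X)[:, None]
        elif X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} covariate(s), got {X.shape[1]}"
            )
        return np.column_stack([np.ones(X.shape[0]), X]), scalar

    def risk(self, X):
        """P(complication) for metric value(s) X; scalar in, scalar out."""
        A, scalar = self._design(X)
        p = expit(A @ self.params_)
        return float(p[0]) if scalar else p

    def predict_proba(self, X):
        p = np.atleast_1d(self.risk(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (np.atleast_1d(self.risk(X)) >= 0.5).astype(int)

    # -- derived quantities --------------------------------------------------

    def tolerance_dose(self, p: float) -> TolerancePoint:
        """Invert the single-covariate model: X_p = (logit(p) - b0) / b1, with
        a delta-method CI from the fit covariance when available."""
        if self.n_features_in_ != 1:
            raise ValueError("tolerance_dose requires a single-covariate model")
        if not 0.0 < p < 1.0:
            raise ValueError("probability level must be in (0, 1)")
        b0, b1 = self.params_
        if b1 == 0:
            raise ValueError("slope is zero: the response curve never crosses p")
        x_p = (logit(p) - b0) / b1
        if self.cov_params_ is None:
            return TolerancePoint(p, float(x_p))
        grad = np.array([-1.0 / b1, -x_p / b1])
        var = float(grad @ self.cov_params_ @ grad)
        half = Z_95 * np.sqrt(max(var, 0.0))
        return TolerancePoint(p, float(x_p), float(x_p - half), float(x_p + half))

    def wald_summary(self) -> pd.DataFrame:
        """Coefficient table: B, SE, Wald = (B/SE)^2, chi-square(1) p, Exp(B);
        covariate rows first, the intercept row labelled 'Constant' last."""
        if not getattr(self, "converged_", False):
            raise NotConvergedError(
                "refusing to summarise a non-converged fit"
                + (" (quasi-complete separation detected)" if getattr(self, "separation_", False) else "")
            )
        if self.cov_params_ is None:
            raise ValueError("no covariance available for Wald statistics")
        order = list(range(1, self.params_.size)) + [0]
        names = self.feature_names_ + ["Constant"]
        return pd.DataFrame(
            {
                "B": self.params_[order],
                "SE": self.bse_[order],
                "Wald": self.wald_[order],
                "Sig": self.pvalues_[order],
                "Exp(B)": np.exp(self.params_[order]),
            },
            index=names,
        )

    def curve(self, x_grid) -> ResponseCurve:
        """Response probability over a grid with a pointwise delta-method band."""
        if self.n_features_in_ != 1:
            raise ValueError("response curves require a single-covariate model")
        x = np.asarray(x_grid, dtype=float)
        A = np.column_stack([np.ones(x.size), x])
        eta = A @ self.params_
        prob = expit(eta)
        if self.cov_params_ is None:
            return ResponseCurve(self.feature_names_[0], x, prob)
        se_eta = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", A, self.cov_params_, A), 0.0))
        return ResponseCurve(
            self.feature_names_[0],
            x,
            prob,
            expit(eta - Z_95 * se_eta),
            expit(eta + Z_95 * se_eta),
        )


# -- functional wrappers ----------------------------------------------------

def fit_logistic(X, y, feature_names=None, max_iter: int = 50,
                 tol: float = 1e-8) -> LogisticNTCP:
    """Fit the logistic dose/volume response model by IRLS."""
    return LogisticNTCP(max_iter=max_iter, tol=tol).fit(X, y, feature_names=feature_names)


def wald_table(fit: LogisticNTCP) -> pd.DataFrame:
    return fit.wald_summary()


def predict_prob(fit: LogisticNTCP, x):
    """Evaluate P(X) = 1/(1+exp(-b0-b1*X))."""
    return fit.risk(x)


def invert_dose(fit: LogisticNTCP, p: float) -> TolerancePoint:
    """Metric value at complication probability p (e.g. p=0.05 for TD5/5)."""
    return fit.tolerance_dose(p)


def response_curve(fit: LogisticNTCP, x_grid) -> ResponseCurve:
    return fit.curve(x_grid)


def covariate_adjustment_check(cohort, metric: str = "D_1.2cc",
                               structure: str = "half_brain",
                               unit: str = "side") -> dict:
    """Does T stage survive adjustment for the dosimetric metric?

    Fits the single-covariate model and the two-covariate model (metric plus
    ordinal T stage) and reports whether the T-stage Wald p exceeds 0.05
    (i.e. whether a stepwise procedure would remove it).
    """
    vals, labels = metric_values(cohort, structure, metric, unit)
    t_ord = []
    for rec in cohort:
        reps = 1 if structure == "brain" or unit == "patient" else 2
        t_ord.extend([float(rec.t_stage.lstrip("T"))] * reps)
    t_ord = np.asarray(t_ord)
    single = fit_logistic(vals, labels, feature_names=[metric])
    joint = fit_logistic(np.column_stack([vals, t_ord]), labels,
                         feature_names=[metric, "T_stage"])
    t_p = float(joint.pvalues_[2])
    metric_p = float(joint.pvalues_[1])
    return {
        "single_fit": single,
        "joint_fit": joint,
        "t_stage_p": t_p,
        "metric_p": metric_p,
        "t_stage_removed": t_p > 0.05,
    }
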