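"""Segmented-regression model fitting.

Two model families are supported on the same four-column design:

* ``linear`` — ordinary least squares on the count scale (the primary
  analysis).  Standard errors use the unbiased residual-variance estimator
  and p-values come from the t distribution with n - 4 degrees of freedom.
* ``negative_binomial`` — NB2 maximum likelihood with a log link (the
  sensitivity analysis).  Coefficients are on the log scale; the dispersion
  theta (variance = mu + mu**2 / theta) is estimated jointly.

The scikit-learn-style :class:`SegmentedITSRegressor` wraps both behind
``fit(X, y)`` / ``predict(X)`` where ``X`` holds global week indices.
"""

from __future__ import annotations

import warnings

import numpy as np
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

from .design import CoefficientSet, InterruptionSpec, WeeklySeries, build_design
from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    NonConvergenceError,
    UndefinedPredictionError,
    UnidentifiableDesignError,
)

_RANK_TOL = 1e-10


def _check_design(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 4:
        raise InvalidInputError("design must be an (n, 4) matrix")
    if y.shape != (X.shape[0],):
        raise InvalidInputError("counts length must match design rows")
    if X.shape[0] <= 4:
        raise InsufficientDataError(
            f"n = {X.shape[0]} rows; more than 4 needed for residual variance"
        )
    if np.linalg.matrix_rank(X, tol=_RANK_TOL * np.linalg.norm(X)) < 4:
        raise UnidentifiableDesignError("design matrix is rank deficient")
    return X, y


def fit_linear(X, y) -> CoefficientSet:
    """Ordinary-least-squares fit of the segmented model.

    Parameters
    ----------
    X : (n, 4) array
        Design matrix from :func:`itsreg.design.build_design`.
    y : (n,) array
        Weekly counts matching the design rows.
    """
    X, y = _check_design(X, y)
    res = sm.OLS(y, X).fit()
    se = np.asarray(res.bse)
    return CoefficientSet(
        i=res.params[0], t=res.params[1], p=res.params[2], s=res.params[3],
        se_i=se[0], se_t=se[1], se_p=se[2], se_s=se[3],
        pvalues=np.asarray(res.pvalues),
        covariance=np.asarray(res.cov_params()),
        model_family="linear",
        n_obs=int(res.nobs),
    )


def fit_negative_binomial(X, y, maxiter: int = 500) -> CoefficientSet:
    """NB2 maximum-likelihood fit with log link on the segmented design.

    Counts must be non-negative integers.  Start values come from a Poisson
    GLM; the reported dispersion is theta = 1 / alpha where alpha is the NB2
    overdispersion (theta -> infinity recovers the Poisson limit).
    """
    X, y = _check_design(X, y)
    if np.any(y < 0) or not np.allclose(y, np.round(y), rtol=0, atol=1e-8):
        raise InvalidInputError("negative-binomial counts must be non-negative integers")
    if np.all(y == 0):
        raise InvalidInputError("all-zero series: NB likelihood is degenerate")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        mu = np.asarray(pois.mu)
        # method-of-moments start for the overdispersion alpha
        alpha0 = float(np.mean(((y - mu) ** 2 - mu) / mu**2))
        alpha0 = min(max(alpha0, 1e-8), 10.0)
        model = sm.NegativeBinomial(y, X, loglike_method="nb2")
        res = last = None
        for a0 in (alpha0, 0.01):
            for method in ("newton", "nm", "lbfgs"):
                try:
                    cand = model.fit(start_params=np.append(pois.params, a0),
                                     method=method, maxiter=maxiter, disp=0)
                except Exception:
                    continue
                ok_params = np.all(np.isfinite(cand.params[:4]))
                ok_cov = np.all(np.isfinite(np.asarray(cand.cov_params())[:4, :4]))
                if cand.mle_retvals.get("converged", False) and ok_params and ok_cov:
                    res = cand
                    break
                if ok_params:
                    last = cand
            if res is not None:
                break

    if res is None:
        raise NonConvergenceError(
            "NB fit did not converge within the iteration budget",
            last_params=None if last is None else np.asarray(last.params),
        )
    beta = np.asarray(res.params[:4])
    cov = np.asarray(res.cov_params())[:4, :4]
    se = np.sqrt(np.diag(cov))
    alpha = float(res.params[4])
    theta = np.inf if alpha <= 0 else 1.0 / alpha
    return CoefficientSet(
        i=beta[0], t=beta[1], p=beta[2], s=beta[3],
        se_i=se[0], se_t=se[1], se_p=se[2], se_s=se[3],
        pvalues=np.asarray(res.pvalues[:4]),
        covariance=cov,
        model_family="negative_binomial",
        dispersion=theta,
        n_obs=int(res.nobs),
        converged=True,
    )


def predict(coeffs: CoefficientSet, week, spec: InterruptionSpec) -> np.ndarray:
    """Model mean at ``week`` (scalar or array) under the fitted family.

    Weeks inside the interruption window are undefined for both segments and
    raise :class:`UndefinedPredictionError`.
    """
    w = np.atleast_1d(np.asarray(week, dtype=float))
    if spec.in_window(w).any():
        raise UndefinedPredictionError(
            "prediction undefined inside the interruption window "
            f"[{spec.gap_start_week}, {spec.gap_end_week}]"
        )
    post = (w >= spec.reference_week).astype(float)
    eta = (coeffs.i + coeffs.t * w + coeffs.p * post
           + coeffs.s * post * (w - spec.reference_week))
    mu = np.exp(eta) if coeffs.model_family == "negative_binomial" else eta
    return mu if np.ndim(week) else float(mu[0])


class SegmentedITSRegressor(RegressorMixin, BaseEstimator):
    """Interrupted time-series regression over weekly counts.

    Fits level-and-slope segmented regression with an excluded transition
    window: a pre-period line, an immediate step at the interruption and a
    changed post-period slope.

    Parameters
    ----------
    gap_start_week, gap_end_week : int, default 63, 66
        Interruption window (inclusive); these weeks are excluded from the fit.
    family : {"linear", "negative_binomial"}, default "linear"
        Model family.  Linear OLS is the primary analysis; NB2 with a log
        link is the overdispersed-count sensitivity model.

    Attributes
    ----------
    coef_set_ : CoefficientSet
        Fitted coefficients with standard errors, p-values and covariance.
    coef_ : ndarray of shape (4,)
        The point estimates (i, t, p, s).
    interruption_ : InterruptionSpec
        The window actually used.
    n_retained_ : int
        Number of weeks entering the fit after window exclusion.

    Examples
    --------
    >>> import numpy as np
    >>> from itsreg.model import SegmentedITSRegressor
    >>> weeks = np.arange(1, 79)
    >>> mu = 200000.0 - 80.0 * weeks
    >>> mu[weeks >= 67] += -98000.0 + 5900.0 * (weeks[weeks >= 67] - 67)
    >>> est = SegmentedITSRegressor().fit(weeks.reshape(-1, 1), mu)
    >>> np.round(est.coef_, 1)
    array([200000.,    -80., -98000.,   5900.])
    """

    def __init__(self, gap_start_week: int = 63, gap_end_week: int = 66,
                 family: str = "linear"):
        self.gap_start_week = gap_start_week
        self.gap_end_week = gap_end_week
        self.family = family

    def _spec(self) -> InterruptionSpec:
        return InterruptionSpec(
            gap_start_week=self.gap_start_week,
            gap_end_week=self.gap_end_week,
            reference_week=self.gap_end_week + 1,
        )

    def fit(self, X, y):
        """Fit the segmented model.

        ``X`` is an (n, 1) array (or length-n vector) of global week
        indices; ``y`` the matching weekly counts."""
        weeks = np.asarray(X).reshape(-1)
        series = WeeklySeries(weeks, np.asarray(y, dtype=float))
        spec = self._spec()
        D, counts, retained = build_design(series, spec)
        if self.family == "linear":
            self.coef_set_ = fit_linear(D, counts)
        elif self.family == "negative_binomial":
            self.coef_set_ = fit_negative_binomial(D, counts)
        else:
            raise InvalidInputError(f"unknown family {self.family!r}")
        self.coef_ = self.coef_set_.estimates
        self.interruption_ = spec
        self.n_retained_ = retained.size
        self.retained_weeks_ = retained
        return self

    def predict(self, X):
        """Model mean for each week in ``X`` (weeks inside the window raise)."""
        if not hasattr(self, "coef_set_"):
            raise InvalidInputError("regressor is not fitted")
        weeks = np.asarray(X).reshape(-1)
        return np.asarray(predict(self.coef_set_, weeks, self.interruption_))
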