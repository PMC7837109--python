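"""Percentage effect metrics and their Monte Carlo confidence intervals.

Two dimensionless metrics summarise the fitted segmented model relative to
the counterfactual baseline level ``B = i + w_ref * t`` at the reference
week ``w_ref`` (the pre-period line continued to the first post-window week):

* **step change** ``-p / B`` — the immediate relative drop at the
  interruption (positive = reduction in activity);
* **weekly increase** ``(t + s) / B`` — the post-period slope as a fraction
  of the baseline level, per week.

For the negative-binomial family the same quantities are formed from
predicted means on the count scale: step change ``1 - exp(p)`` at the
reference week, and weekly increase as the *average* per-week rise of the
predicted mean over the post-period horizon ``K`` (default 11 weeks, the
post span of the reference 78-week design),
``exp(p) * (exp(K * (t + s)) - 1) / K``, both relative to the
counterfactual level ``exp(i + w_ref * t)``.  Averaging over the horizon
makes the metric comparable to the linear family's constant slope when the
underlying recovery is close to linear; the log-link mean path is convex,
so its instantaneous slope at the reference week alone would understate
the recovery.

Uncertainty is propagated by Monte Carlo simulation: coefficient vectors
are redrawn from normals centred on the estimates, the metric is evaluated
per draw, and an equal-tailed percentile interval is taken.  By default each
coefficient is drawn independently with its own standard error; drawing from
the full multivariate normal over the coefficient covariance is available
via ``sampling="multivariate"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .design import CoefficientSet, InterruptionSpec
from .exceptions import DegenerateBaselineError, InvalidInputError, UnstableMetricError

METRIC_NAMES = ("step_change", "weekly_increase")

#: Maximum tolerated fraction of Monte Carlo draws with non-positive baseline.
MAX_DISCARD_FRACTION = 0.01

#: Post-period horizon (weeks) over which the negative-binomial weekly
#: increase is averaged: the post span of the reference 78-week design.
NB_WEEKLY_INCREASE_HORIZON = 11


@dataclass(frozen=True)
class MetricEstimate:
    """A percentage metric with its Monte Carlo interval.

    ``point``, ``ci_low`` and ``ci_high`` are proportions (0.511 = 51.1%).
    """

    name: str
    point: float
    ci_low: float
    ci_high: float
    n_reps: int
    seed: int

    def __post_init__(self):
        if self.name not in METRIC_NAMES:
            raise InvalidInputError(f"unknown metric {self.name!r}")
        if self.n_reps < 1000:
            raise InvalidInputError("reported intervals require n_reps >= 1000")

    def as_percent(self) -> tuple[float, float, float]:
        """(point, low, high) on the percentage scale, one-decimal rounding."""
        return (round(100 * self.point, 1),
                round(100 * self.ci_low, 1),
                round(100 * self.ci_high, 1))


def _metric_from_draws(draws: np.ndarray, name: str, w_ref: int,
                       family: str,
                       horizon: int = NB_WEEKLY_INCREASE_HORIZON) -> np.ndarray:
    """Evaluate a metric on an (n, 4) array of (i, t, p, s) vectors.

    Returns NaN where the baseline is non-positive (linear family only;
    the log-link baseline is always positive).
    """
    i, t, p, s = draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3]
    if family == "negative_binomial":
        if name == "step_change":
            return 1.0 - np.exp(p)
        return np.exp(p) * (np.exp(horizon * (t + s)) - 1.0) / horizon
    baseline = i + w_ref * t
    with np.errstate(divide="ignore", invalid="ignore"):
        if name == "step_change":
            out = -p / baseline
        else:
            out = (t + s) / baseline
    out = np.where(baseline > 0, out, np.nan)
    return out


def _point(coeffs: CoefficientSet, name: str, spec: InterruptionSpec) -> float:
    val = _metric_from_draws(coeffs.estimates[None, :], name,
                             spec.reference_week, coeffs.model_family)[0]
    if np.isnan(val):
        raise DegenerateBaselineError(
            f"baseline i + {spec.reference_week}*t is non-positive; "
            "percentage metrics undefined"
        )
    return float(val)


def step_change(coeffs: CoefficientSet, spec: InterruptionSpec | None = None) -> float:
    """Immediate relative drop at the interruption, ``-p / (i + w_ref t)``.

    Positive values mean a reduction in activity.
    """
    return _point(coeffs, "step_change", spec or InterruptionSpec())


def weekly_increase(coeffs: CoefficientSet, spec: InterruptionSpec | None = None) -> float:
    """Post-interruption weekly slope as a fraction of the baseline,
    ``(t + s) / (i + w_ref t)``."""
    return _point(coeffs, "weekly_increase", spec or InterruptionSpec())


def monte_carlo_ci(
    coeffs: CoefficientSet,
    metric: str,
    spec: InterruptionSpec | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    sampling: str = "independent",
) -> tuple[float, float]:
    """95% Monte Carlo confidence interval for a metric.

    Draws ``n_reps`` coefficient vectors — each component independently
    normal around its estimate with its standard error by default, or from
    the full multivariate normal with ``sampling="multivariate"`` —
    evaluates the metric per draw, and returns the (2.5th, 97.5th)
    percentiles.  Deterministic given ``seed``.

    Draws hitting a non-positive baseline are discarded with a warning;
    if more than 1% are discarded an :class:`UnstableMetricError` is raised.
    """
    if metric not in METRIC_NAMES:
        raise InvalidInputError(f"unknown metric {metric!r}")
    if n_reps < 1000:
        raise InvalidInputError("n_reps >= 1000 required for reported intervals")
    spec = spec or InterruptionSpec()
    ses = coeffs.standard_errors
    if not np.all(np.isfinite(ses)):
        raise InvalidInputError("all standard errors must be present and finite")

    rng = np.random.default_rng(seed)
    if sampling == "independent":
        draws = coeffs.estimates + ses * rng.standard_normal((n_reps, 4))
    elif sampling == "multivariate":
        if not np.all(np.isfinite(coeffs.covariance)):
            raise InvalidInputError("multivariate sampling needs a full covariance")
        draws = rng.multivariate_normal(coeffs.estimates, coeffs.covariance,
                                        size=n_reps, method="cholesky")
    else:
        raise InvalidInputError(f"unknown sampling {sampling!r}")

    vals = _metric_from_draws(draws, metric, spec.reference_week,
                              coeffs.model_family)
    bad = np.isnan(vals)
    if bad.any():
        frac = bad.mean()
        if frac > MAX_DISCARD_FRACTION:
            raise UnstableMetricError(
                f"{100 * frac:.1f}% of draws hit a non-positive baseline"
            )
        warnings.warn(
            f"discarded {int(bad.sum())} of {n_reps} Monte Carlo draws with "
            "non-positive baseline", RuntimeWarning, stacklevel=2,
        )
        vals = vals[~bad]
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def metric_estimate(
    coeffs: CoefficientSet,
    metric: str,
    spec: InterruptionSpec | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    sampling: str = "independent",
) -> MetricEstimate:
    """Point estimate plus Monte Carlo interval, bundled."""
    spec = spec or InterruptionSpec()
    lo, hi = monte_carlo_ci(coeffs, metric, spec, n_reps=n_reps, seed=seed,
                            sampling=sampling)
    return MetricEstimate(name=metric, point=_point(coeffs, metric, spec),
                          ci_low=lo, ci_high=hi, n_reps=n_reps, seed=seed)
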