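"""Weekly series container, interruption window, and the segmented design matrix.

The analysis models weekly event counts on a global week index where week 1
is the first 7-day bin starting 1 January 2019 (week 53 therefore begins
1 January 2020; ISO week numbering is *not* used).  The interruption is a
contiguous block of transition weeks that belongs to neither the pre- nor
the post-period segment; those weeks are excluded from every fit.

For a retained week ``w`` the design row is::

    (1,  w,  I[w >= reference_week],  I[w >= reference_week] * (w - reference_week))

i.e. intercept, linear week term, post-interruption step indicator, and
weeks-since-interruption interaction.  The interaction originates at the
reference week (zero there), so the fitted level at the reference week is
``i + w_ref * t + p`` and the step-change metric ``-p / (i + w_ref * t)``
attributes the whole immediate drop to the step coefficient ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .exceptions import InvalidInputError, ItsRegError, UnidentifiableDesignError

#: Calendar origin of the global week index: week 1 begins on this date.
WEEK_ONE_START = date(2019, 1, 1)

#: Columns of the segmented design matrix, in order.
DESIGN_COLUMNS = ("intercept", "week", "interruption", "weeks_since")


def week_index_from_date(d: date) -> int:
    """Global week index of calendar date ``d`` (consecutive 7-day bins
    from 1 Jan 2019; 11 Mar 2020 falls in week 63)."""
    return (d - WEEK_ONE_START).days // 7 + 1


@dataclass(frozen=True)
class InterruptionSpec:
    """The excluded interruption window and the post-period reference week.

    Defaults encode the 4-week transition window 11 Mar - 7 Apr 2020 on the
    global week index (weeks 63-66), with week 67 the first post-interruption
    week.

    Parameters
    ----------
    gap_start_week, gap_end_week : int
        First and last week inside the interruption window (inclusive).
    reference_week : int
        First week after the interruption; must equal ``gap_end_week + 1``.
    """

    gap_start_week: int = 63
    gap_end_week: int = 66
    reference_week: int = 67

    def __post_init__(self):
        if self.gap_start_week > self.gap_end_week:
            raise InvalidInputError(
                f"gap_start_week ({self.gap_start_week}) must not exceed "
                f"gap_end_week ({self.gap_end_week})"
            )
        if self.reference_week != self.gap_end_week + 1:
            raise InvalidInputError(
                f"reference_week must be gap_end_week + 1 "
                f"(got {self.reference_week}, expected {self.gap_end_week + 1})"
            )

    def in_window(self, week) -> np.ndarray:
        """Boolean mask: which of ``week`` fall inside the excluded window."""
        w = np.asarray(week)
        return (w >= self.gap_start_week) & (w <= self.gap_end_week)


@dataclass
class WeeklySeries:
    """Ordered weekly event counts on the global week index.

    Parameters
    ----------
    week : array-like of int
        Strictly increasing global week indices (week 1 = first week of 2019).
    count : array-like
        Non-negative event counts, one per week.
    label : str, optional
        Subgroup identifier carried through reports.
    """

    week: np.ndarray
    count: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.week = np.asarray(self.week, dtype=int)
        self.count = np.asarray(self.count, dtype=float)
        if self.week.ndim != 1 or self.count.ndim != 1:
            raise InvalidInputError("week and count must be one-dimensional")
        if self.week.shape != self.count.shape:
            raise InvalidInputError(
                f"week and count lengths differ ({self.week.size} vs {self.count.size})"
            )
        if self.week.size and np.any(np.diff(self.week) <= 0):
            raise InvalidInputError("week indices must be strictly increasing")
        if np.any(self.week < 1):
            raise InvalidInputError("week indices must be positive")
        if np.any(self.count < 0):
            raise InvalidInputError("counts must be non-negative")

    def __len__(self) -> int:
        return self.week.size

    def retained(self, spec: InterruptionSpec) -> "WeeklySeries":
        """The series with interruption-window weeks removed."""
        keep = ~spec.in_window(self.week)
        return WeeklySeries(self.week[keep], self.count[keep], label=self.label)


@dataclass
class CoefficientSet:
    """Fitted segmented-regression coefficients.

    ``i``/``t``/``p``/``s`` are the intercept, week slope, interruption step
    and post-interruption slope-change coefficients.  For the linear family
    they are on the count scale; for the negative-binomial family they are on
    the log-link scale and ``dispersion`` carries the NB2 shape parameter
    theta (variance = mu + mu**2 / theta).
    """

    i: float
    t: float
    p: float
    s: float
    se_i: float
    se_t: float
    se_p: float
    se_s: float
    pvalues: np.ndarray = field(default_factory=lambda: np.full(4, np.nan))
    covariance: np.ndarray = field(default_factory=lambda: np.full((4, 4), np.nan))
    model_family: str = "linear"
    dispersion: float | None = None
    n_obs: int | None = None
    converged: bool = True

    def __post_init__(self):
        self.pvalues = np.asarray(self.pvalues, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.model_family not in ("linear", "negative_binomial"):
            raise InvalidInputError(f"unknown model_family {self.model_family!r}")
        for name, se in (("se_i", self.se_i), ("se_t", self.se_t),
                         ("se_p", self.se_p), ("se_s", self.se_s)):
            if not se >= 0:
                raise InvalidInputError(f"{name} must be non-negative, got {se}")
        if self.pvalues.shape != (4,):
            raise InvalidInputError("pvalues must have length 4")
        if self.covariance.shape != (4, 4):
            raise InvalidInputError("covariance must be 4x4")
        finite = np.isfinite(self.covariance)
        if finite.all():
            if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
                raise InvalidInputError("covariance must be symmetric")
            diag = np.diag(self.covariance)
            ses = np.array([self.se_i, self.se_t, self.se_p, self.se_s]) ** 2
            if not np.allclose(diag, ses, rtol=1e-6, atol=1e-12):
                raise InvalidInputError(
                    "covariance diagonal must equal squared standard errors"
                )

    @property
    def estimates(self) -> np.ndarray:
        return np.array([self.i, self.t, self.p, self.s])

    @property
    def standard_errors(self) -> np.ndarray:
        return np.array([self.se_i, self.se_t, self.se_p, self.se_s])


def build_design(series: WeeklySeries, spec: InterruptionSpec):
    """Construct the segmented-regression design from a weekly series.

    Interruption-window weeks are excluded.  Returns ``(X, y, weeks)`` where
    ``X`` is the (n, 4) design matrix over retained weeks in week order,
    ``y`` the matching counts and ``weeks`` the retained week indices.

    Raises
    ------
    UnidentifiableDesignError
        If fewer than 4 retained rows remain.
    ItsRegError
        If a window week survives exclusion (internal consistency check).
    """
    kept = series.retained(spec)
    if len(kept) < 4:
        raise UnidentifiableDesignError(
            f"only {len(kept)} retained weeks; at least 4 needed to identify "
            "the four coefficients"
        )
    w = kept.week
    if spec.in_window(w).any():  # pragma: no cover - defensive
        raise ItsRegError("internal consistency error: window week retained")
    post = (w >= spec.reference_week).astype(float)
    X = np.column_stack([
        np.ones_like(w, dtype=float),
        w.astype(float),
        post,
        post * (w - spec.reference_week),
    ])
    return X, kept.count.copy(), w.copy()
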