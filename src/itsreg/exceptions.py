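"""Exception hierarchy for itsreg.

All package errors derive from :class:`ItsRegError` so callers can catch one
base class at pipeline boundaries.
"""


class ItsRegError(Exception):
    """Base class for all itsreg errors."""


class UnidentifiableDesignError(ItsRegError):
    """Design matrix is rank deficient or has too few rows to identify
    the four segmented-regression coefficients."""


class InsufficientDataError(ItsRegError):
    """Too few observations for the requested fit."""


class InvalidInputError(ItsRegError):
    """Input values violate a precondition (e.g. non-integer counts
    passed to the negative-binomial model)."""


class NonConvergenceError(ItsRegError):
    """Iterative fit failed to converge within its iteration budget.

    Carries the last parameter iterate in ``last_params`` when available.
    """

    def __init__(self, message, last_params=None):
        super().__init__(message)
        self.last_params = last_params


class DegenerateBaselineError(ItsRegError):
    """The counterfactual baseline level i + w_ref * t is non-positive,
    so the percentage metrics are undefined."""


class UnstableMetricError(ItsRegError):
    """More than the tolerated share of Monte Carlo draws produced a
    non-positive baseline."""


class UndefinedPredictionError(ItsRegError):
    """Prediction requested for a week inside the interruption window,
    where neither fitted segment applies."""


class InputFormatError(ItsRegError):
    """A delimited input file is malformed (missing column, duplicate
    week, unparseable date, ...)."""


class ConfigError(ItsRegError):
    """A run or synthetic-data configuration is invalid."""
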