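"""Reference values from the national English ED weekly-attendance analysis.

These are the printed headline outputs of the national interrupted
time-series analysis of weekly emergency-department attendances (weeks 1-78,
i.e. Jan 2019 - Jun 2020, with the 4-week interruption window at weeks
63-66).  They serve three purposes in this package: default truth for the
synthetic generator, worked-example inputs in the docs, and fixed inputs for
the reproduction checks.
"""

from __future__ import annotations

import numpy as np

from .design import CoefficientSet, InterruptionSpec


def reference_interruption() -> InterruptionSpec:
    """The reference interruption window: weeks 63-66, reference week 67."""
    return InterruptionSpec(63, 66, 67)


def reference_fit() -> CoefficientSet:
    """The reference linear segmented-regression fit for all-attendance
    weekly counts (coefficients on the count scale, week 67 reference).

    The covariance carries the squared standard errors on its diagonal and
    zero off-diagonals, matching the independent-normal uncertainty
    propagation used for the published intervals.
    """
    se = np.array([1646.5, 45.4, 4319.2, 537.5])
    return CoefficientSet(
        i=198_577.6, t=-82.3, p=-98_616.1, s=5883.0,
        se_i=se[0], se_t=se[1], se_p=se[2], se_s=se[3],
        pvalues=np.array([5e-4, 0.074, 5e-4, 5e-4]),
        covariance=np.diag(se**2),
        model_family="linear",
    )


#: Reference subgroup step-change intervals (proportions): point, low, high.
#: The "all" row is the overall analysis; "ambulance" and "walk in" are the
#: arrival-mode levels, whose step changes bracket the overall value.
REFERENCE_STEP_CHANGE_INTERVALS = {
    "all": (0.511, 0.464, 0.557),
    "ambulance": (0.319, 0.282, 0.357),
    "walk in": (0.603, 0.535, 0.676),
}

#: Share of all attendances arriving by each mode (ambulance vs walk-in).
REFERENCE_ARRIVAL_MODE_SHARES = {"ambulance": 0.327, "walk in": 0.673}
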