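"""Batch subgroup analysis and significance flagging.

Runs the full fit-and-metrics pipeline on every level of every requested
grouping column (plus an overall "All" series), and flags levels whose
step change or recovery slope differs significantly from the overall
analysis.  The default significance rule is non-overlap of 95% intervals:
a subgroup is "larger"/"faster" when its whole interval lies above the
overall interval, "smaller"/"slower" when entirely below, and
"not_different" otherwise (including whenever either interval is
undefined).  An alternative rule — the overall *point* falling outside the
subgroup interval — is available via ``rule="point_outside"``.

Levels whose fit fails are reported with an explicit status, never
silently dropped; analysis of the remaining levels is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import InterruptionSpec, WeeklySeries, build_design
from .exceptions import ConfigError, ItsRegError
from .metrics import MetricEstimate, metric_estimate
from .model import fit_linear
from .synthetic import level_seed

FLAG_STEP = ("larger", "smaller", "not_different")
FLAG_SLOPE = ("faster", "slower", "not_different")


@dataclass
class SubgroupResult:
    """One row of a subgroup report."""

    grouping: str
    subgroup: str
    step_change: MetricEstimate | None
    weekly_increase: MetricEstimate | None
    n_weeks: int
    flag_step: str = "not_different"
    flag_slope: str = "not_different"
    status: str = "ok"   # "ok" or a short failure description


def flag_significance(
    subgroup: MetricEstimate | None,
    overall: MetricEstimate | None,
    rule: str = "nonoverlap",
    direction_labels: tuple[str, str] = ("larger", "smaller"),
) -> str:
    """Compare a subgroup interval with the overall interval.

    Returns the first label of ``direction_labels`` when the subgroup is
    significantly above the overall, the second when below, else
    "not_different".  Degenerate or missing intervals default to
    "not_different".
    """
    above, below = direction_labels
    if subgroup is None or overall is None:
        return "not_different"
    if rule == "nonoverlap":
        if subgroup.ci_low > overall.ci_high:
            return above
        if subgroup.ci_high < overall.ci_low:
            return below
        return "not_different"
    if rule == "point_outside":
        if overall.point < subgroup.ci_low:
            return above
        if overall.point > subgroup.ci_high:
            return below
        return "not_different"
    raise ConfigError(f"unknown significance rule {rule!r}")


def _analyse_series(series: WeeklySeries, spec: InterruptionSpec,
                    n_reps: int, seed: int):
    X, y, weeks = build_design(series, spec)
    coeffs = fit_linear(X, y)
    step = metric_estimate(coeffs, "step_change", spec, n_reps=n_reps, seed=seed)
    slope = metric_estimate(coeffs, "weekly_increase", spec, n_reps=n_reps, seed=seed)
    return step, slope, weeks.size


def run_subgroup_analysis(
    data: pd.DataFrame,
    groupings: list[str],
    spec: InterruptionSpec | None = None,
    n_reps: int = 10_000,
    seed: int = 0,
    rule: str = "nonoverlap",
) -> list[SubgroupResult]:
    """Fit the ITS model and both metrics for every subgroup level.

    ``data`` is a long-format table with columns ``week`` and ``count``
    plus categorical columns naming each grouping.  A wide table (one row
    per week, counts already aggregated per level in a ``grouping`` /
    ``subgroup`` pair of columns, as produced by the synthetic generator)
    is also accepted.  The overall series is the per-week sum over the
    levels of the first grouping (each grouping is assumed to partition
    all events).

    Returns one :class:`SubgroupResult` per level plus an overall result
    labelled ``All``/``All`` (first element).  Per-level Monte Carlo seeds
    derive from the master seed and the level label, so the full run is
    reproducible bit-for-bit from ``seed``.
    """
    spec = spec or InterruptionSpec()
    if "week" not in data.columns or "count" not in data.columns:
        raise ConfigError("data must have 'week' and 'count' columns")

    long_format = {"grouping", "subgroup"} <= set(data.columns)
    if not long_format:
        missing = [g for g in groupings if g not in data.columns]
        if missing:
            raise ConfigError(f"unknown grouping column(s): {missing}")

    def levels_of(grouping: str):
        if long_format:
            sub = data[data["grouping"] == grouping]
            if sub.empty:
                raise ConfigError(f"unknown grouping column(s): ['{grouping}']")
            for lvl, chunk in sub.groupby("subgroup", sort=True):
                yield str(lvl), chunk[["week", "count"]]
        else:
            for lvl, chunk in data.groupby(grouping, sort=True):
                agg = chunk.groupby("week", as_index=False)["count"].sum()
                yield str(lvl), agg

    # Overall series: per-week sum across the first grouping's levels.
    first = groupings[0]
    pieces = [chunk for _, chunk in levels_of(first)]
    overall_tab = (pd.concat(pieces).groupby("week", as_index=False)["count"].sum())
    overall_series = WeeklySeries(overall_tab["week"].to_numpy(),
                                  overall_tab["count"].to_numpy(), label="All")
    o_step, o_slope, o_n = _analyse_series(
        overall_series, spec, n_reps, level_seed(seed, "All", "All"))
    results = [SubgroupResult("All", "All", o_step, o_slope, o_n)]

    for grouping in groupings:
        for lvl, tab in levels_of(grouping):
            series = WeeklySeries(tab["week"].to_numpy(),
                                  tab["count"].to_numpy(), label=lvl)
            lseed = level_seed(seed, grouping, lvl)
            kept = series.retained(spec)
            if np.count_nonzero(kept.count) < 4:
                results.append(SubgroupResult(
                    grouping, lvl, None, None, len(kept),
                    status="insufficient_data"))
                continue
            try:
                step, slope, n_weeks = _analyse_series(series, spec, n_reps, lseed)
            except ItsRegError as exc:
                results.append(SubgroupResult(
                    grouping, lvl, None, None, len(kept),
                    status=f"fit_failed: {exc}"))
                continue
            results.append(SubgroupResult(
                grouping, lvl, step, slope, n_weeks,
                flag_step=flag_significance(step, o_step, rule,
                                            ("larger", "smaller")),
                flag_slope=flag_significance(slope, o_slope, rule,
                                             ("faster", "slower")),
            ))
    return results


def subgroup_report(results: list[SubgroupResult]) -> pd.DataFrame:
    """Tabulate subgroup results (percentages to one decimal)."""
    rows = []
    for r in results:
        def pct(est, idx):
            return None if est is None else est.as_percent()[idx]
        rows.append({
            "grouping": r.grouping, "subgroup": r.subgroup,
            "step_change_pct": pct(r.step_change, 0),
            "step_ci_low_pct": pct(r.step_change, 1),
            "step_ci_high_pct": pct(r.step_change, 2),
            "weekly_increase_pct": pct(r.weekly_increase, 0),
            "weekly_ci_low_pct": pct(r.weekly_increase, 1),
            "weekly_ci_high_pct": pct(r.weekly_increase, 2),
            "n_weeks": r.n_weeks,
            "flag_step": r.flag_step, "flag_slope": r.flag_slope,
            "status": r.status,
        })
    return pd.DataFrame(rows)
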