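"""Delimited-text input and report output.

Input tables are comma- or tab-separated with a header.  Weeks may be given
either as the integer global index (column ``week``) or as an ISO-8601
week-start date (column ``week_start``), which is converted to the global
index with week 1 beginning 1 Jan 2019.  Gaps in the week sequence are
tolerated with a logged warning; duplicate weeks are rejected with row
numbers.
"""

from __future__ import annotations

import logging
from datetime import date

import numpy as np
import pandas as pd

from .design import CoefficientSet, InterruptionSpec, week_index_from_date
from .exceptions import InputFormatError
from .model import predict

logger = logging.getLogger("itsreg")


def read_weekly_counts(path) -> pd.DataFrame:
    """Read a weekly-count table from a delimited text file.

    Returns a DataFrame with an integer ``week`` column, a numeric
    ``count`` column, and any extra (subgroup) columns passed through.
    """
    try:
        with open(path) as fh:
            header = fh.readline()
        sep = "\t" if "\t" in header else ","
        df = pd.read_csv(path, sep=sep)
    except OSError as exc:
        raise InputFormatError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:
        raise InputFormatError(f"cannot parse {path}: {exc}") from exc
    if df.empty:
        raise InputFormatError(f"{path}: no data rows")

    cols = {c.strip(): c for c in df.columns}
    if "count" not in cols:
        raise InputFormatError(f"{path}: missing required column 'count'")

    if "week" in cols:
        weeks_raw = df[cols["week"]]
        weeks = pd.to_numeric(weeks_raw, errors="coerce")
        bad = weeks.isna() | (weeks != weeks.round())
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise InputFormatError(f"{path}: non-integer week at line {row}")
        week_idx = weeks.astype(int)
    elif "week_start" in cols:
        parsed = pd.to_datetime(df[cols["week_start"]], errors="coerce",
                                format="ISO8601")
        if parsed.isna().any():
            row = int(parsed.isna().idxmax()) + 2
            raise InputFormatError(f"{path}: unparseable date at line {row}")
        week_idx = parsed.dt.date.map(week_index_from_date).astype(int)
    else:
        raise InputFormatError(
            f"{path}: need a 'week' (integer) or 'week_start' (date) column"
        )

    counts = pd.to_numeric(df[cols["count"]], errors="coerce")
    if counts.isna().any():
        row = int(counts.isna().idxmax()) + 2
        raise InputFormatError(f"{path}: unparseable count at line {row}")

    out = df.copy()
    out["week"] = week_idx.to_numpy()
    out["count"] = counts.to_numpy()
    if "week_start" in cols and cols["week_start"] != "week":
        out = out.drop(columns=[cols["week_start"]])

    subgroup_cols = [c for c in out.columns if c not in ("week", "count")]
    dup_keys = subgroup_cols if subgroup_cols else []
    dup_mask = out.duplicated(subset=["week"] + dup_keys, keep=False)
    if dup_mask.any():
        lines = [str(i + 2) for i in out.index[dup_mask]]
        raise InputFormatError(
            f"{path}: duplicate week entries at lines {', '.join(lines)}"
        )

    if not subgroup_cols:
        w = np.sort(out["week"].to_numpy())
        gaps = np.setdiff1d(np.arange(w.min(), w.max() + 1), w)
        if gaps.size:
            logger.warning("%s: missing week(s) %s; fitting proceeds on "
                           "available weeks", path, gaps.tolist())
    return out


def coefficient_report(coeffs: CoefficientSet) -> pd.DataFrame:
    """Term / estimate / standard-error / p-value table (one-decimal counts)."""
    terms = ["(intercept)", "week number", "interruption (binary)",
             "week number * interruption"]
    df = pd.DataFrame({
        "term": terms,
        "estimate": np.round(coeffs.estimates, 1),
        "standard_error": np.round(coeffs.standard_errors, 1),
        "p_value": coeffs.pvalues,
    })
    if coeffs.model_family == "negative_binomial":
        df["estimate"] = coeffs.estimates  # log scale: keep full precision
        df["standard_error"] = coeffs.standard_errors
    return df


def metric_report(estimates) -> pd.DataFrame:
    """Metric table: metric, point_pct, ci_low_pct, ci_high_pct, n_reps, seed."""
    rows = []
    for est in estimates:
        point, lo, hi = est.as_percent()
        rows.append({"metric": est.name, "point_pct": point,
                     "ci_low_pct": lo, "ci_high_pct": hi,
                     "n_reps": est.n_reps, "seed": est.seed})
    return pd.DataFrame(rows)


def fitted_table(coeffs: CoefficientSet, series, spec: InterruptionSpec) -> pd.DataFrame:
    """Per-week observed vs fitted values for plotting (window weeks get
    no fitted value)."""
    fitted = np.full(len(series), np.nan)
    outside = ~spec.in_window(series.week)
    if outside.any():
        fitted[outside] = np.asarray(
            predict(coeffs, series.week[outside], spec))
    return pd.DataFrame({
        "week": series.week, "observed": series.count, "fitted": fitted,
        "in_interruption_window": ~outside,
    })
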