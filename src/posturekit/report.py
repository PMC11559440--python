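"""Cohort-level report tables and the labor-savings arithmetic.

Everything here is a table export: demographics before/after exclusion,
median/IQR of every summary statistic, histogram bin tables (2-h bins
for whole-day durations, 1-h for the 12-hour windows, 1-tph for
transition frequencies), and scatter exports for the duration
interrelationship plots (with the 12-hour cap boundary).  Figures are a
thin optional layer over these tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import DURATION_COLUMNS, FPT_COLUMNS, WINDOWS
from .groups import GROUPS


def percent_of(count: float, total: float, decimals: int = 0) -> float:
    """Share of a total as a percentage, rounded for printing."""
    if total == 0:
        return 0.0
    value = 100.0 * count / total
    return round(value, decimals) if decimals else float(round(value))


def combined_bin_percentage(bin_counts, total: int, decimals: int = 0) -> float:
    """Aggregate histogram bins and express them as a share of the cohort."""
    return percent_of(float(np.sum(bin_counts)), total, decimals)


def labor_savings(
    patient_days: float, hours_per_patient_day: float, wage: float
) -> tuple[float, int]:
    """Nurse-hours replaced by automated monitoring, and their cost.

    ``hours = patient_days x hours_per_patient_day``; cost is hours at
    the hourly wage, rounded to the nearest currency unit.
    """
    if patient_days < 0 or hours_per_patient_day < 0 or wage < 0:
        raise ValueError("labor_savings inputs must be nonnegative")
    hours = patient_days * hours_per_patient_day
    return hours, int(round(hours * wage))


def demographics_table(admissions: pd.DataFrame, retained_mrns) -> pd.DataFrame:
    """Age and sex distributions before and after data exclusion."""
    rows = {}
    for label, sub in (
        ("before", admissions),
        ("after", admissions[admissions["mrn"].isin(set(retained_mrns))]),
    ):
        age = sub["age"].astype(float)
        n = len(sub)
        sex_counts = sub["sex"].value_counts()
        row = {
            "n": n,
            "age_mean": round(float(age.mean()), 1) if n else np.nan,
            "age_sd": round(float(age.std(ddof=1)), 1) if n > 1 else np.nan,
            "age_median": round(float(age.median()), 1) if n else np.nan,
            "age_q1": round(float(age.quantile(0.25)), 1) if n else np.nan,
            "age_q3": round(float(age.quantile(0.75)), 1) if n else np.nan,
        }
        for sex in ("male", "female", "unknown"):
            c = int(sex_counts.get(sex, 0))
            row[f"{sex}_n"] = c
            row[f"{sex}_pct"] = percent_of(c, n, 1)
        rows[label] = row
    return pd.DataFrame(rows).T


def quartile_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Median (Q1-Q3) of each duration and FPT statistic, by window."""
    rows = []
    for window in WINDOWS:
        row: dict[str, float] = {"window": window}
        for g in GROUPS + ["FPT"]:
            col = f"FPT-{window}" if g == "FPT" else f"{g}-{window}"
            vals = summaries[col].dropna().astype(float)
            row[f"{g}_median"] = float(vals.median())
            row[f"{g}_q1"] = float(vals.quantile(0.25))
            row[f"{g}_q3"] = float(vals.quantile(0.75))
        rows.append(row)
    return pd.DataFrame(rows).set_index("window")


def histogram_table(values, bin_width: float, lo: float, hi: float) -> pd.DataFrame:
    """Fixed-width histogram with counts and cohort percentages.

    Bins are half-open [left, right) except the last, which includes
    ``hi`` so the bin counts always sum to the number of values.
    """
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    table = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
        }
    )
    table["pct"] = [percent_of(c, len(vals), 1) for c in counts]
    return table


#: default bin widths per statistic family (inferred figure axes; configurable)
HISTOGRAM_SPECS = {
    "WD": (2.0, 0.0, 24.0),
    "DT": (1.0, 0.0, 12.0),
    "NT": (1.0, 0.0, 12.0),
    "FPT": (1.0, 0.0, 24.0),
}


def histogram_bundle(summaries: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Histogram tables for every duration and FPT statistic."""
    out = {}
    for col in DURATION_COLUMNS:
        if col.startswith("UserDefined"):
            continue
        window = col.rsplit("-", 1)[1]
        width, lo, hi = HISTOGRAM_SPECS[window]
        out[col] = histogram_table(summaries[col], width, lo, hi)
    for col in FPT_COLUMNS:
        width, lo, hi = HISTOGRAM_SPECS["FPT"]
        out[col] = histogram_table(summaries[col], width, lo, hi)
    return out


def scatter_export(summaries: pd.DataFrame) -> pd.DataFrame:
    """Point table for the duration interrelationship plots.

    Includes Rest = Lying + Reclined per window and the window cap
    (12 h) as the boundary-line constant.
    """
    cols = [
        "mrn",
        "Lying-DT",
        "Reclined-DT",
        "Upright-DT",
        "Rest-DT",
        "Lying-NT",
        "Reclined-NT",
        "Upright-NT",
        "Rest-NT",
    ]
    out = summaries[cols].copy()
    out["window_cap_hours"] = 12.0
    return out


def quantity_report(quantity: pd.DataFrame, retained_mrns) -> dict:
    """Data-quantity medians and day-count histograms for retained patients."""
    sub = quantity[quantity["mrn"].isin(set(retained_mrns))]
    return {
        "n_patients": len(sub),
        "median_total_days": float(sub["total_days"].median()),
        "median_analysis_days": float(sub["analysis_days"].median()),
        "total_days_hist": histogram_table(
            sub["total_days"], 1.0, 0.0, max(1.0, float(sub["total_days"].max()) + 1)
        ),
        "analysis_days_hist": histogram_table(
            sub["analysis_days"], 1.0, 0.0, max(1.0, float(sub["analysis_days"].max()) + 1)
        ),
    }
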