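"""Per-patient data-quantity, posture-duration and transition statistics.

A day is the local calendar date.  A day qualifies as an analysis day
when it holds at least 22 hours of recordings — with one recording per
15 s that is at least 5280 recordings; hours of data are measured as
recording-count x 15 s, so the two thresholds coincide.  Duration and
transition statistics are computed on analysis days only; patients with
no analysis day are excluded from them (total days is still reported).

Windows: whole day (WD), daytime DT = [07:00:00, 19:00:00) local, and
nighttime NT = the complementary 12 hours.  Durations are the per-day
within-window group proportions averaged over analysis days and scaled
to hours (x24 for WD, x12 for DT/NT).  A posture transition is a change
between grid-adjacent timestamps among Lying/Reclined/Upright only;
pairs across a gap, across midnight, or spanning the DT/NT boundary are
not counted (boundary-spanning pairs belong to no window).  Transition
frequency (FPT) is per-day transitions divided by that day's in-window
hours of data, averaged over analysis days.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import GRID_SECONDS
from .groups import GROUPS, PostureGroup

logger = logging.getLogger(__name__)

DT_START_HOUR = 7
DT_END_HOUR = 19
ANALYSIS_DAY_HOURS = 22.0

TRANSITION_GROUPS = frozenset(
    {PostureGroup.LYING.value, PostureGroup.RECLINED.value, PostureGroup.UPRIGHT.value}
)

WINDOWS = ("WD", "DT", "NT")

#: Table-style column order of the per-patient summary statistics.
DURATION_COLUMNS = [f"{g}-{w}" for w in WINDOWS for g in GROUPS]
FPT_COLUMNS = [f"FPT-{w}" for w in WINDOWS]
REST_COLUMNS = ["Rest-DT", "Rest-NT"]
SUMMARY_COLUMNS = ["mrn", "total_days", "analysis_days"] + DURATION_COLUMNS + FPT_COLUMNS + REST_COLUMNS


def analysis_day_min_recordings(hours: float = ANALYSIS_DAY_HOURS) -> int:
    """Minimum recordings for a day to qualify as an analysis day."""
    return math.ceil(hours * 3600 / GRID_SECONDS)


def _annotate(series: pd.DataFrame, dt_start: int, dt_end: int) -> pd.DataFrame:
    df = series.sort_values(["mrn", "timestamp"], kind="stable").reset_index(drop=True)
    df["date"] = df["timestamp"].dt.normalize()
    hour = df["timestamp"].dt.hour
    df["window"] = np.where((hour >= dt_start) & (hour < dt_end), "DT", "NT")
    return df


def split_days(
    series: pd.DataFrame,
    threshold_hours: float = ANALYSIS_DAY_HOURS,
) -> pd.DataFrame:
    """Per (patient, calendar date) recording counts and analysis-day flag."""
    df = series.copy()
    df["date"] = df["timestamp"].dt.normalize()
    table = df.groupby(["mrn", "date"], sort=True).size().rename("n_recordings").reset_index()
    table["hours_of_data"] = table["n_recordings"] * GRID_SECONDS / 3600.0
    table["is_analysis_day"] = table["n_recordings"] >= analysis_day_min_recordings(threshold_hours)
    return table


def _pair_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Grid-adjacent same-patient same-date pairs, with transition flags."""
    g = df["group"].to_numpy()
    ts = df["timestamp"].to_numpy()
    mrn = df["mrn"].to_numpy()
    date = df["date"].to_numpy()
    step = np.timedelta64(GRID_SECONDS, "s")
    adj = (mrn[:-1] == mrn[1:]) & ((ts[1:] - ts[:-1]) == step) & (date[:-1] == date[1:])
    lru = np.isin(g, list(TRANSITION_GROUPS))
    trans = adj & lru[:-1] & lru[1:] & (g[:-1] != g[1:])
    win = df["window"].to_numpy()
    pairs = pd.DataFrame(
        {
            "mrn": mrn[:-1],
            "date": date[:-1],
            "is_transition": trans,
            "window_first": win[:-1],
            "window_second": win[1:],
            "adjacent": adj,
        }
    )
    return pairs


def transition_count(day_series: pd.DataFrame) -> int:
    """Transitions within one contiguous day/window slice.

    Counts ordered grid-adjacent pairs whose groups both lie in
    {Lying, Reclined, Upright} and differ; gaps break adjacency.
    """
    df = day_series.sort_values("timestamp", kind="stable")
    g = df["group"].to_numpy()
    ts = df["timestamp"].to_numpy()
    if len(g) < 2:
        return 0
    step = np.timedelta64(GRID_SECONDS, "s")
    adj = (ts[1:] - ts[:-1]) == step
    lru = np.isin(g, list(TRANSITION_GROUPS))
    return int((adj & lru[:-1] & lru[1:] & (g[:-1] != g[1:])).sum())


def _day_window_counts(df: pd.DataFrame) -> pd.DataFrame:
    """Per (mrn, date): recordings and transitions, per window and WD."""
    sizes = df.groupby(["mrn", "date", "window"], sort=True).size().unstack(fill_value=0)
    for w in ("DT", "NT"):
        if w not in sizes.columns:
            sizes[w] = 0
    out = sizes.rename(columns={"DT": "n_DT", "NT": "n_NT"})[["n_DT", "n_NT"]].copy()
    out["n_WD"] = out["n_DT"] + out["n_NT"]

    pairs = _pair_frame(df)
    key = ["mrn", "date"]
    t_wd = pairs.loc[pairs["is_transition"]].groupby(key).size()
    same_window = pairs["window_first"] == pairs["window_second"]
    t_dt = pairs.loc[pairs["is_transition"] & same_window & (pairs["window_first"] == "DT")].groupby(key).size()
    t_nt = pairs.loc[pairs["is_transition"] & same_window & (pairs["window_first"] == "NT")].groupby(key).size()
    out["t_WD"] = t_wd.reindex(out.index, fill_value=0)
    out["t_DT"] = t_dt.reindex(out.index, fill_value=0)
    out["t_NT"] = t_nt.reindex(out.index, fill_value=0)
    return out


def duration_stats(
    series: pd.DataFrame,
    window: str,
    threshold_hours: float = ANALYSIS_DAY_HOURS,
    dt_start: int = DT_START_HOUR,
    dt_end: int = DT_END_HOUR,
) -> pd.DataFrame:
    """Average hours per group in one window, per patient with >=1 analysis day."""
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}, got {window!r}")
    df = _annotate(series, dt_start, dt_end)
    days = split_days(df, threshold_hours)
    analysis_keys = days.loc[days["is_analysis_day"], ["mrn", "date"]]
    df = df.merge(analysis_keys, on=["mrn", "date"], how="inner")
    if window != "WD":
        df = df.loc[df["window"] == window]
    scale = 24.0 if window == "WD" else 12.0
    counts = (
        df.groupby(["mrn", "date", "group"], sort=True, observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=GROUPS, fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    hours = props.groupby(level="mrn", sort=True).mean() * scale
    hours.columns = [f"{g}-{window}" for g in hours.columns]
    return hours


def fpt_stats(
    series: pd.DataFrame,
    window: str,
    threshold_hours: float = ANALYSIS_DAY_HOURS,
    dt_start: int = DT_START_HOUR,
    dt_end: int = DT_END_HOUR,
) -> pd.Series:
    """Average transitions-per-hour in one window, per patient."""
    if window not in WINDOWS:
        raise ValueError(f"window must be one of {WINDOWS}, got {window!r}")
    df = _annotate(series, dt_start, dt_end)
    days = split_days(df, threshold_hours)
    analysis_keys = days.loc[days["is_analysis_day"], ["mrn", "date"]].set_index(["mrn", "date"]).index
    counts = _day_window_counts(df)
    counts = counts.loc[counts.index.isin(analysis_keys)]
    n = counts[f"n_{window}"]
    hours = n * GRID_SECONDS / 3600.0
    tph = (counts[f"t_{window}"] / hours).where(n > 0)
    return tph.groupby(level="mrn", sort=True).mean().dropna().rename(f"FPT-{window}")


def summarize_patients(
    series: pd.DataFrame,
    threshold_hours: float = ANALYSIS_DAY_HOURS,
    dt_start: int = DT_START_HOUR,
    dt_end: int = DT_END_HOUR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the full per-patient summary table.

    Returns ``(summaries, quantity)``.  ``summaries`` has one row per
    patient with at least one analysis day and the 20 statistics plus
    the derived Rest columns; ``quantity`` has total/analysis day counts
    for every patient in the input (including excluded ones).
    """
    df = _annotate(series, dt_start, dt_end)
    days = split_days(df, threshold_hours)
    quantity = (
        days.groupby("mrn", sort=True)
        .agg(total_days=("date", "size"), analysis_days=("is_analysis_day", "sum"))
        .reset_index()
    )
    quantity["analysis_days"] = quantity["analysis_days"].astype(int)

    retained = quantity.loc[quantity["analysis_days"] >= 1, "mrn"]
    n_excluded = len(quantity) - len(retained)
    if n_excluded:
        logger.info("%d patients had no analysis day and are excluded from statistics", n_excluded)
    if retained.empty:
        return pd.DataFrame(columns=SUMMARY_COLUMNS), quantity

    parts = [quantity.set_index("mrn").loc[retained]]
    for window in WINDOWS:
        parts.append(duration_stats(df, window, threshold_hours, dt_start, dt_end))
    for window in WINDOWS:
        parts.append(fpt_stats(df, window, threshold_hours, dt_start, dt_end))
    summary = pd.concat(parts, axis=1)
    summary["Rest-DT"] = summary["Lying-DT"] + summary["Reclined-DT"]
    summary["Rest-NT"] = summary["Lying-NT"] + summary["Reclined-NT"]
    summary = summary.reset_index().rename(columns={"index": "mrn"})
    return summary[[c for c in SUMMARY_COLUMNS if c in summary.columns]], quantity


def quantity_regression(quantity: pd.DataFrame) -> tuple[float, float]:
    """OLS of analysis days on total days; returns (intercept, slope)."""
    x = quantity["total_days"].to_numpy(dtype=float)
    y = quantity["analysis_days"].to_numpy(dtype=float)
    if len(x) < 2 or np.unique(x).size < 2:
        raise ValueError("regression needs >=2 patients with distinct total_days")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)
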