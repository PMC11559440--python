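"""Readers and writers for the recording and admissions tables.

Canonical dialect: UTF-8, comma-separated, header row, ISO-8601 naive
local timestamps.  Recordings sit on a 15-second grid; rows off the grid
are rejected (strict mode) or snapped to the nearest grid point (lenient
mode).  The reader never silently drops rows: every input row is either
parsed or returned in the reject table.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GRID_SECONDS = 15

RECORDING_COLUMNS = ["mrn", "file_id", "device_serial", "timestamp", "posture"]
ADMISSION_COLUMNS = ["mrn", "admit_time", "discharge_time", "age", "sex"]

SEX_VALUES = {"male", "female", "unknown"}

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%S"


class TelemetryError(Exception):
    """Base class for telemetry I/O failures."""


class SchemaError(TelemetryError):
    """Header or table-level constraint violated."""


class ParseError(TelemetryError):
    """A field could not be parsed; message carries the row number."""


class ValidationError(TelemetryError):
    """A parsed record violates a domain invariant."""


def tokenize_recording(posture_string: str | float | None) -> list[str]:
    """Split a raw posture string into upper-cased code tokens.

    Splits on runs of whitespace, preserves order, and returns an empty
    list for blank/missing input.
    """
    if posture_string is None or (isinstance(posture_string, float) and np.isnan(posture_string)):
        return []
    return str(posture_string).upper().split()


def _check_header(actual: Sequence[str], expected: Sequence[str], path: str | Path) -> None:
    if list(actual) != list(expected):
        raise SchemaError(
            f"{path}: unexpected columns {list(actual)!r}; expected {list(expected)!r}"
        )


def _parse_timestamps(raw: pd.Series, path: str | Path, column: str) -> pd.Series:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    bad = parsed.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header row
        raise ParseError(f"{path}: malformed {column} at row {row}: {raw[bad.idxmax()]!r}")
    return parsed


def on_grid(timestamps: pd.Series, grid_seconds: int = GRID_SECONDS) -> pd.Series:
    """Boolean mask: timestamp lies exactly on the recording grid."""
    ns = timestamps.astype("int64")
    return pd.Series(ns % (grid_seconds * 1_000_000_000) == 0, index=timestamps.index)


def snap_to_grid(timestamps: pd.Series, grid_seconds: int = GRID_SECONDS) -> pd.Series:
    """Round timestamps to the nearest grid point (lenient mode)."""
    return timestamps.dt.round(f"{grid_seconds}s")


def read_recordings(
    paths: str | Path | Iterable[str | Path],
    lenient: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read one or more recordings CSVs.

    Returns ``(records, rejected)``.  ``records`` has the canonical
    columns with parsed timestamps, ordered within patient by timestamp
    (ties keep file order); ``rejected`` holds off-grid rows (strict
    mode) with a ``reject_reason`` column.  In lenient mode off-grid
    rows are snapped to the grid and logged instead of rejected.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for path in paths:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        _check_header(df.columns, RECORDING_COLUMNS, path)
        df["timestamp"] = _parse_timestamps(df["timestamp"], path, "timestamp")
        for col in ("mrn", "file_id", "device_serial"):
            if (df[col].astype(str).str.strip() == "").any():
                raise ValidationError(f"{path}: empty {col} value")
        frames.append(df)
    if frames:
        records = pd.concat(frames, ignore_index=True)
    else:
        records = pd.DataFrame(columns=RECORDING_COLUMNS)
        records["timestamp"] = pd.to_datetime(records["timestamp"])

    grid_ok = on_grid(records["timestamp"]) if len(records) else pd.Series(dtype=bool)
    if lenient and len(records) and not grid_ok.all():
        n_bad = int((~grid_ok).sum())
        logger.warning("snapped %d off-grid timestamps to the 15-s grid", n_bad)
        records.loc[~grid_ok, "timestamp"] = snap_to_grid(records.loc[~grid_ok, "timestamp"])
        rejected = records.iloc[0:0].copy()
        rejected["reject_reason"] = pd.Series(dtype=str)
    else:
        rejected = records.loc[~grid_ok].copy() if len(records) else records.iloc[0:0].copy()
        rejected["reject_reason"] = "off_grid"
        if len(rejected):
            logger.warning("rejected %d off-grid rows", len(rejected))
        records = records.loc[grid_ok] if len(records) else records

    records = records.sort_values(["mrn", "timestamp"], kind="stable").reset_index(drop=True)
    return records, rejected.reset_index(drop=True)


def read_admissions(path: str | Path) -> pd.DataFrame:
    """Read the admissions table; one row per patient."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_header(df.columns, ADMISSION_COLUMNS, path)
    if df["mrn"].duplicated().any():
        dup = df.loc[df["mrn"].duplicated(), "mrn"].iloc[0]
        raise SchemaError(f"{path}: duplicate MRN {dup!r}")
    df["admit_time"] = _parse_timestamps(df["admit_time"], path, "admit_time")
    df["discharge_time"] = _parse_timestamps(df["discharge_time"], path, "discharge_time")
    both = df["admit_time"].notna() & df["discharge_time"].notna()
    bad = both & (df["admit_time"] >= df["discharge_time"])
    if bad.any():
        raise ValidationError(f"{path}: admit_time >= discharge_time for MRN {df.loc[bad, 'mrn'].iloc[0]!r}")
    age = pd.to_numeric(df["age"].replace("", None), errors="raise")
    df["age"] = age.astype("Float64")
    sex = df["sex"].str.strip().str.lower().replace("", "unknown")
    unknown_sex = ~sex.isin(SEX_VALUES)
    if unknown_sex.any():
        raise ValidationError(f"{path}: invalid sex value {df.loc[unknown_sex, 'sex'].iloc[0]!r}")
    df["sex"] = sex
    return df.reset_index(drop=True)


def write_recordings(records: pd.DataFrame, path: str | Path) -> None:
    out = records[RECORDING_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False)


def write_admissions(admissions: pd.DataFrame, path: str | Path) -> None:
    out = admissions[ADMISSION_COLUMNS].copy()
    out["admit_time"] = out["admit_time"].dt.strftime(TIMESTAMP_FORMAT)
    out["discharge_time"] = out["discharge_time"].dt.strftime(TIMESTAMP_FORMAT)
    out.to_csv(path, index=False)
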