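"""Two-stage cleaning: time-inconsistency exclusion, then overlap exclusion.

Stage 1 drops recordings timestamped outside the patient's admission
window (boundaries inclusive — admit/discharge times are approximate,
so boundary recordings are kept).  Patients with no admission record
cannot be checked and are excluded entirely.  Stage 2 first collapses
exact duplicate rows (a re-exported identical row carries no ambiguity),
then flags every (mrn, timestamp) pair that still holds two or more
recordings: with no way to tell which stream is correct, all colliding
recordings are excluded.  The report accounts for every patient and
recording at each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import RECORDING_COLUMNS

logger = logging.getLogger(__name__)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Share as a percentage, rounded the way the report prints it."""
    if denominator == 0:
        return 0.0
    return round(100.0 * numerator / denominator, decimals)


@dataclass
class StageCounts:
    patients_in: int
    recordings_in: int
    patients_out: int
    recordings_out: int

    @property
    def patients_excluded(self) -> int:
        return self.patients_in - self.patients_out

    @property
    def recordings_excluded(self) -> int:
        return self.recordings_in - self.recordings_out


@dataclass
class CleaningReport:
    """Flow accounting for the two cleaning stages."""

    inconsistency: StageCounts
    overlap: StageCounts
    deduplicated: int = 0
    patients_without_admission: int = 0
    extra: dict = field(default_factory=dict)

    @property
    def patients_in(self) -> int:
        return self.inconsistency.patients_in

    @property
    def recordings_in(self) -> int:
        return self.inconsistency.recordings_in

    @property
    def patients_out(self) -> int:
        return self.overlap.patients_out

    @property
    def recordings_out(self) -> int:
        return self.overlap.recordings_out

    @property
    def pct_patients_excluded(self) -> float:
        return percent(self.patients_in - self.patients_out, self.patients_in)

    @property
    def pct_recordings_excluded(self) -> float:
        return percent(self.recordings_in - self.recordings_out, self.recordings_in)

    def to_dict(self) -> dict:
        return {
            "patients_in": self.patients_in,
            "recordings_in": self.recordings_in,
            "stages": {
                "inconsistency": vars(self.inconsistency)
                | {
                    "patients_excluded": self.inconsistency.patients_excluded,
                    "recordings_excluded": self.inconsistency.recordings_excluded,
                },
                "overlap": vars(self.overlap)
                | {
                    "patients_excluded": self.overlap.patients_excluded,
                    "recordings_excluded": self.overlap.recordings_excluded,
                },
            },
            "deduplicated": self.deduplicated,
            "patients_without_admission": self.patients_without_admission,
            "patients_out": self.patients_out,
            "recordings_out": self.recordings_out,
            "pct_patients_excluded": self.pct_patients_excluded,
            "pct_recordings_excluded": self.pct_recordings_excluded,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def flag_inconsistent(records: pd.DataFrame, admissions: pd.DataFrame) -> tuple[pd.Series, set]:
    """Flag recordings outside [admit, discharge] for their patient.

    Returns ``(flags, missing_mrns)`` where ``flags`` is aligned with
    ``records`` and ``missing_mrns`` lists patients with no admission
    record (the check cannot be applied; the caller excludes them).
    Boundary timestamps equal to admit or discharge are kept.
    """
    adm = admissions.set_index("mrn")
    known = records["mrn"].isin(adm.index)
    missing_mrns = set(records.loc[~known, "mrn"].unique())
    if missing_mrns:
        logger.warning("%d patients have recordings but no admission record", len(missing_mrns))
    admit = records["mrn"].map(adm["admit_time"])
    discharge = records["mrn"].map(adm["discharge_time"])
    flags = known & ((records["timestamp"] < admit) | (records["timestamp"] > discharge))
    return flags.fillna(False).astype(bool), missing_mrns


def flag_overlap(records: pd.DataFrame, extend_to_device_stream: bool = False) -> tuple[pd.DataFrame, pd.Series]:
    """Deduplicate exact copies, then flag colliding (mrn, timestamp) rows.

    Returns ``(deduplicated records, flags)`` with flags aligned to the
    deduplicated frame.  With ``extend_to_device_stream`` every row of a
    (mrn, file, device) stream involved in any collision is flagged, for
    sensitivity analysis; the default flags colliding timestamps only.
    """
    dedup = records.drop_duplicates(subset=RECORDING_COLUMNS, keep="first").copy()
    sizes = dedup.groupby(["mrn", "timestamp"], sort=False)["timestamp"].transform("size")
    flags = sizes > 1
    if extend_to_device_stream and flags.any():
        streams = dedup.loc[flags, ["mrn", "file_id", "device_serial"]].drop_duplicates()
        key = pd.MultiIndex.from_frame(dedup[["mrn", "file_id", "device_serial"]])
        flags = flags | key.isin(pd.MultiIndex.from_frame(streams))
    return dedup, pd.Series(flags, index=dedup.index)


def apply_exclusions(
    records: pd.DataFrame,
    admissions: pd.DataFrame,
    extend_to_device_stream: bool = False,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run both cleaning stages in order and account for every row.

    Stage order is inconsistency first, then overlap.  Patients left
    with zero recordings disappear from the cohort; the report carries
    stage-wise patient/recording counts and the overall excluded
    percentages of the initial totals.
    """
    patients_in = int(records["mrn"].nunique())
    recordings_in = int(len(records))

    inc_flags, missing = flag_inconsistent(records, admissions)
    keep = ~inc_flags & ~records["mrn"].isin(missing)
    stage1 = records.loc[keep]
    s1 = StageCounts(patients_in, recordings_in, int(stage1["mrn"].nunique()), int(len(stage1)))

    dedup, ovl_flags = flag_overlap(stage1, extend_to_device_stream=extend_to_device_stream)
    n_dedup = len(stage1) - len(dedup)
    clean = dedup.loc[~ovl_flags]
    s2 = StageCounts(s1.patients_out, int(len(dedup)), int(clean["mrn"].nunique()), int(len(clean)))

    report = CleaningReport(
        inconsistency=s1,
        overlap=s2,
        deduplicated=int(n_dedup),
        patients_without_admission=len(missing),
    )
    clean = clean.sort_values(["mrn", "timestamp"], kind="stable").reset_index(drop=True)
    return clean, report
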