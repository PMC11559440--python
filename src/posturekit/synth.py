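"""Synthetic posture-telemetry cohorts with ground truth.

Generates per-patient 15-second posture streams from habit archetypes
(a first-order bout model: bout lengths are geometric, bout groups are
drawn i.i.d. from daytime/nighttime weight vectors, bouts are truncated
at the day/night window boundary so window proportions track the
weights), then injects the two error types the cleaning stage must
catch — overlap collisions copied from another patient's stream and
out-of-admission-window recordings — plus isolated single-timestamp
group flips for the smoother.  Every injected error is flagged in the
ground-truth sidecar.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .groups import (
    GROUPS,
    LYING_CODES,
    PostureGroup,
    classify_string,
)

GRID_NS = tio.GRID_SECONDS * 1_000_000_000
STEPS_PER_HOUR = 3600 // tio.GRID_SECONDS
STEPS_PER_DAY = 24 * STEPS_PER_HOUR

#: groups an archetype draws from (UserDefined is never generated)
WEIGHT_GROUPS = [
    PostureGroup.LYING.value,
    PostureGroup.RECLINED.value,
    PostureGroup.UPRIGHT.value,
    PostureGroup.UNKNOWN.value,
]

GROUP_CODES = {
    PostureGroup.LYING.value: sorted(LYING_CODES),
    PostureGroup.RECLINED.value: ["U45"],
    PostureGroup.UPRIGHT.value: ["U90", "U90", "WLK"],  # WLK rarer
    PostureGroup.UNKNOWN.value: ["UNK"],
}

TRUTH_COLUMNS = [
    "mrn",
    "file_id",
    "device_serial",
    "timestamp",
    "is_overlap_injected",
    "is_out_of_window",
    "is_noise_flip",
    "true_group",
    "archetype",
]


class ConfigurationError(ValueError):
    """Invalid generator configuration."""


def _check_weights(weights: dict[str, float], name: str) -> dict[str, float]:
    w = {g: float(weights.get(g, 0.0)) for g in WEIGHT_GROUPS}
    vals = np.array(list(w.values()))
    if (vals < 0).any() or not np.isclose(vals.sum(), 1.0, atol=1e-9):
        raise ConfigurationError(f"{name} weights must be nonnegative and sum to 1, got {weights}")
    return w


@dataclass
class ArchetypeSpec:
    """One posture-habit archetype: window-specific group weights + bout model."""

    name: str
    daytime_group_weights: dict[str, float]
    nighttime_group_weights: dict[str, float]
    mean_bout_len: float = 10.0
    noise_rate: float = 0.0
    permutation_rate: float = 0.25
    long_permutation_rate: float = 0.02

    def __post_init__(self) -> None:
        self.daytime_group_weights = _check_weights(self.daytime_group_weights, "daytime")
        self.nighttime_group_weights = _check_weights(self.nighttime_group_weights, "nighttime")
        if self.mean_bout_len < 1:
            raise ConfigurationError("mean_bout_len must be >= 1")
        if not 0 <= self.noise_rate <= 0.2:
            raise ConfigurationError("noise_rate must be in [0, 0.2]")


@dataclass
class CohortConfig:
    n_patients: int
    days_per_patient: int | tuple[int, int]
    archetypes: list[ArchetypeSpec]
    archetype_mix: list[float]
    frac_overlap_patients: float = 0.0
    frac_inconsistent_patients: float = 0.0
    frac_incomplete_days: float = 0.0
    seed: int = 0
    start_date: str = "2019-03-01"

    def __post_init__(self) -> None:
        mix = np.asarray(self.archetype_mix, dtype=float)
        if len(mix) != len(self.archetypes) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ConfigurationError("archetype_mix must be a probability vector over archetypes")
        for frac in (
            self.frac_overlap_patients,
            self.frac_inconsistent_patients,
            self.frac_incomplete_days,
        ):
            if not 0 <= frac <= 1:
                raise ConfigurationError("all proportions must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text())
        archetypes = [ArchetypeSpec(**a) for a in raw.pop("archetypes")]
        days = raw.pop("days_per_patient")
        if isinstance(days, list):
            days = tuple(days)
        return cls(archetypes=archetypes, days_per_patient=days, **raw)


@dataclass
class Cohort:
    """In-memory synthetic cohort: data plus row-aligned ground truth."""

    recordings: pd.DataFrame
    admissions: pd.DataFrame
    truth: pd.DataFrame
    patients: pd.DataFrame = field(default_factory=pd.DataFrame)

    def sort(self) -> "Cohort":
        order = self.recordings.sort_values(
            ["mrn", "timestamp", "file_id", "device_serial", "posture"], kind="stable"
        ).index
        self.recordings = self.recordings.loc[order].reset_index(drop=True)
        self.truth = self.truth.loc[order].reset_index(drop=True)
        return self


def _draw_bout_lengths(rng: np.random.Generator, total: int, mean_len: float) -> np.ndarray:
    p = 1.0 / mean_len
    lens = rng.geometric(p, size=total)  # worst case: all bouts length 1
    cum = np.cumsum(lens)
    n = int(np.searchsorted(cum, total)) + 1
    lens = lens[:n].copy()
    lens[-1] -= cum[n - 1] - total
    return lens


def _segment_postures(
    rng: np.random.Generator,
    length: int,
    weights: dict[str, float],
    archetype: ArchetypeSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one within-window segment; returns (groups, posture strings)."""
    lens = _draw_bout_lengths(rng, length, archetype.mean_bout_len)
    probs = np.array([weights[g] for g in WEIGHT_GROUPS])
    bout_groups = rng.choice(len(WEIGHT_GROUPS), size=len(lens), p=probs)
    bout_codes = np.array(
        [GROUP_CODES[WEIGHT_GROUPS[g]][rng.integers(len(GROUP_CODES[WEIGHT_GROUPS[g]]))] for g in bout_groups],
        dtype=object,
    )
    groups = np.repeat(np.array([WEIGHT_GROUPS[g] for g in bout_groups], dtype=object), lens)
    postures = np.repeat(bout_codes, lens)

    # Multi-code permutations at bout boundaries: the slot saw the end of
    # the previous posture and the start of the new one.  Only emitted
    # when the combined string still classifies to the new bout's group,
    # so consolidation recovers the true group sequence exactly.
    starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
    for b in range(1, len(lens)):
        if rng.random() >= archetype.permutation_rate:
            continue
        prev_code, cur_code = bout_codes[b - 1], bout_codes[b]
        if prev_code == cur_code:
            continue
        candidate = f"{prev_code} {cur_code}"
        if rng.random() < archetype.long_permutation_rate:
            extra = GROUP_CODES[WEIGHT_GROUPS[bout_groups[b]]]
            candidate = f"{prev_code} {extra[rng.integers(len(extra))]} {cur_code}"
        if classify_string(candidate).value == WEIGHT_GROUPS[bout_groups[b]]:
            postures[starts[b]] = candidate
    return groups, postures


def _inject_noise_flips(
    rng: np.random.Generator,
    groups: np.ndarray,
    postures: np.ndarray,
    noise_rate: float,
) -> np.ndarray:
    """Flip isolated single timestamps to a random different group.

    Flip sites are drawn at ``noise_rate`` per interior timestamp but
    placed only where the surrounding 5-window is constant and at least
    3 steps from any other flip, so a 3-window majority vote reverts
    every flip and nothing else near it.  Returns the flip mask;
    ``groups`` keeps the pre-flip truth, ``postures`` is mutated.
    """
    n = len(groups)
    flipped = np.zeros(n, dtype=bool)
    if noise_rate <= 0 or n < 5:
        return flipped
    i = np.arange(2, n - 2)
    candidates = i[
        (groups[i] == groups[i - 1])
        & (groups[i] == groups[i + 1])
        & (groups[i] == groups[i - 2])
        & (groups[i] == groups[i + 2])
    ]
    n_target = rng.binomial(n - 2, noise_rate)
    order = rng.permutation(len(candidates))
    blocked = np.zeros(n, dtype=bool)
    chosen = []
    for j in order:
        pos = candidates[j]
        if blocked[pos]:
            continue
        chosen.append(pos)
        blocked[max(0, pos - 2) : pos + 3] = True
        if len(chosen) >= n_target:
            break
    for pos in chosen:
        others = [g for g in WEIGHT_GROUPS if g != groups[pos]]
        new = others[rng.integers(len(others))]
        codes = GROUP_CODES[new]
        postures[pos] = codes[rng.integers(len(codes))]
        flipped[pos] = True
    return flipped


def generate_patient_series(
    archetype: ArchetypeSpec,
    n_days: int,
    admit: pd.Timestamp | str,
    seed: int,
    mrn: str = "P0001",
    age: float | None = None,
    sex: str = "unknown",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one patient's full stay.

    Returns ``(recordings, admission, truth)``.  Recordings cover the
    15-s grid over [admit, admit + n_days); the device serial changes
    daily (devices are recharged and swapped) and the file id every
    three days.
    """
    if n_days < 1:
        raise ConfigurationError("n_days must be >= 1")
    admit = pd.Timestamp(admit).floor("15s")
    rng = np.random.default_rng(seed)
    n_steps = n_days * STEPS_PER_DAY
    ts = admit + pd.to_timedelta(np.arange(n_steps) * tio.GRID_SECONDS, unit="s")
    sod = ts.hour * 3600 + ts.minute * 60 + ts.second
    is_dt = (sod >= 7 * 3600) & (sod < 19 * 3600)

    # window-homogeneous segments
    change = np.flatnonzero(np.diff(is_dt.astype(int)) != 0) + 1
    bounds = np.concatenate(([0], change, [n_steps]))
    group_parts, posture_parts = [], []
    for a, b in zip(bounds[:-1], bounds[1:]):
        weights = archetype.daytime_group_weights if is_dt[a] else archetype.nighttime_group_weights
        g, p = _segment_postures(rng, b - a, weights, archetype)
        group_parts.append(g)
        posture_parts.append(p)
    groups = np.concatenate(group_parts)
    postures = np.concatenate(posture_parts)
    flips = _inject_noise_flips(rng, groups, postures, archetype.noise_rate)

    day_idx = np.arange(n_steps) // STEPS_PER_DAY
    recordings = pd.DataFrame(
        {
            "mrn": mrn,
            "file_id": np.char.add(f"F{mrn}-", (day_idx // 3).astype(str)),
            "device_serial": np.char.add(f"D{mrn}-", day_idx.astype(str)),
            "timestamp": ts,
            "posture": postures,
        }
    )
    admission = pd.DataFrame(
        {
            "mrn": [mrn],
            "admit_time": [admit],
            "discharge_time": [admit + pd.Timedelta(days=n_days)],
            "age": pd.array([age], dtype="Float64"),
            "sex": [sex],
        }
    )
    truth = recordings[["mrn", "file_id", "device_serial", "timestamp"]].copy()
    truth["is_overlap_injected"] = False
    truth["is_out_of_window"] = False
    truth["is_noise_flip"] = flips
    truth["true_group"] = groups
    truth["archetype"] = archetype.name
    return recordings, admission, truth


def _select_patients(rng: np.random.Generator, mrns: np.ndarray, frac: float) -> np.ndarray:
    n_sel = int(round(frac * len(mrns)))
    return rng.choice(mrns, size=n_sel, replace=False)


def inject_overlap(
    cohort: Cohort,
    frac: float,
    seed: int,
    min_len: int = 40,
    max_len: int = 240,
) -> Cohort:
    """Copy another patient's segment onto a fraction of patients.

    For each selected victim, a contiguous run of a donor patient's
    recordings (donor's own device serial and file id, hence distinct
    provenance) is relabeled with the victim's MRN at timestamps the
    victim already occupies, creating collisions.  Injected rows are
    flagged ``is_overlap_injected`` in the ground truth.
    """
    mrns = cohort.recordings["mrn"].unique()
    if frac > 0 and len(mrns) < 2:
        raise ConfigurationError("overlap injection needs >= 2 patients")
    rng = np.random.default_rng(seed)
    victims = _select_patients(rng, mrns, frac)
    new_rec, new_truth = [], []
    by_mrn = {m: g.sort_values("timestamp") for m, g in cohort.recordings.groupby("mrn")}
    truth_by_idx = cohort.truth
    for victim in victims:
        donor = rng.choice(mrns[mrns != victim])
        vic = by_mrn[victim]
        don = by_mrn[donor]
        L = int(rng.integers(min_len, min(max_len, len(vic), len(don)) + 1))
        vs = int(rng.integers(0, len(vic) - L + 1))
        ds = int(rng.integers(0, len(don) - L + 1))
        seg = don.iloc[ds : ds + L]
        rows = pd.DataFrame(
            {
                "mrn": victim,
                "file_id": seg["file_id"].to_numpy(),
                "device_serial": seg["device_serial"].to_numpy(),
                "timestamp": vic["timestamp"].iloc[vs : vs + L].to_numpy(),
                "posture": seg["posture"].to_numpy(),
            }
        )
        t = rows[["mrn", "file_id", "device_serial", "timestamp"]].copy()
        t["is_overlap_injected"] = True
        t["is_out_of_window"] = False
        t["is_noise_flip"] = False
        t["true_group"] = truth_by_idx.loc[seg.index, "true_group"].to_numpy()
        t["archetype"] = truth_by_idx.loc[vic.index[0], "archetype"]
        new_rec.append(rows)
        new_truth.append(t)
    if new_rec:
        cohort.recordings = pd.concat([cohort.recordings, *new_rec], ignore_index=True)
        cohort.truth = pd.concat([cohort.truth, *new_truth], ignore_index=True)
    return cohort


def inject_inconsistency(
    cohort: Cohort,
    frac: float,
    seed: int,
    max_extension_hours: float = 48.0,
    min_extension_hours: float = 1.0,
) -> Cohort:
    """Add grid-aligned recordings strictly outside the admission window.

    The extension can be long ("up to days"): its length is drawn
    uniformly between the hour bounds.  Rows never touch the inclusive
    [admit, discharge] boundaries and are flagged ``is_out_of_window``.
    """
    mrns = cohort.recordings["mrn"].unique()
    rng = np.random.default_rng(seed)
    selected = _select_patients(rng, mrns, frac)
    adm = cohort.admissions.set_index("mrn")
    new_rec, new_truth = [], []
    arch = cohort.truth.drop_duplicates("mrn").set_index("mrn")["archetype"]
    for m in selected:
        after = bool(rng.random() < 0.5)
        hours = float(rng.uniform(min_extension_hours, max_extension_hours))
        k = int(hours * STEPS_PER_HOUR)
        if after:
            base = adm.loc[m, "discharge_time"]
            offsets = np.arange(1, k + 1)
        else:
            base = adm.loc[m, "admit_time"]
            offsets = -np.arange(1, k + 1)
        ts = base + pd.to_timedelta(offsets * tio.GRID_SECONDS, unit="s")
        codes = rng.choice(GROUP_CODES[PostureGroup.LYING.value] + ["U45", "U90"], size=k)
        rows = pd.DataFrame(
            {
                "mrn": m,
                "file_id": f"F{m}-oow",
                "device_serial": f"D{m}-oow",
                "timestamp": ts,
                "posture": codes,
            }
        )
        t = rows[["mrn", "file_id", "device_serial", "timestamp"]].copy()
        t["is_overlap_injected"] = False
        t["is_out_of_window"] = True
        t["is_noise_flip"] = False
        t["true_group"] = [classify_string(c).value for c in codes]
        t["archetype"] = arch.get(m, "")
        new_rec.append(rows)
        new_truth.append(t)
    if new_rec:
        cohort.recordings = pd.concat([cohort.recordings, *new_rec], ignore_index=True)
        cohort.truth = pd.concat([cohort.truth, *new_truth], ignore_index=True)
    return cohort


def _drop_incomplete_days(cohort: Cohort, frac: float, seed: int) -> Cohort:
    """Remove a contiguous >2 h block from a fraction of patient-days."""
    if frac <= 0:
        return cohort
    rng = np.random.default_rng(seed)
    rec = cohort.recordings
    date = rec["timestamp"].dt.normalize()
    keys = pd.MultiIndex.from_arrays([rec["mrn"], date]).unique()
    n_sel = int(round(frac * len(keys)))
    sel = rng.choice(len(keys), size=n_sel, replace=False)
    drop_idx = []
    grouped = rec.groupby([rec["mrn"], date]).indices
    for i in sel:
        idx = np.sort(grouped[keys[i]])
        max_drop = min(len(idx), 12 * STEPS_PER_HOUR)
        n_drop = int(rng.integers(2 * STEPS_PER_HOUR + 1, max_drop + 1))
        start = int(rng.integers(0, len(idx) - n_drop + 1))
        drop_idx.append(idx[start : start + n_drop])
    drop = np.concatenate(drop_idx) if drop_idx else np.array([], dtype=int)
    keep = np.setdiff1d(np.arange(len(rec)), drop)
    cohort.recordings = rec.iloc[keep].reset_index(drop=True)
    cohort.truth = cohort.truth.iloc[keep].reset_index(drop=True)
    return cohort


def _empty_recordings() -> pd.DataFrame:
    df = pd.DataFrame(columns=tio.RECORDING_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def _empty_admissions() -> pd.DataFrame:
    df = pd.DataFrame(columns=tio.ADMISSION_COLUMNS)
    df["admit_time"] = pd.to_datetime(df["admit_time"])
    df["discharge_time"] = pd.to_datetime(df["discharge_time"])
    df["age"] = df["age"].astype("Float64")
    return df


def _empty_truth() -> pd.DataFrame:
    df = pd.DataFrame(columns=TRUTH_COLUMNS)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    for col in ("is_overlap_injected", "is_out_of_window", "is_noise_flip"):
        df[col] = df[col].astype(bool)
    return df


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a full cohort per the configuration (single global seed)."""
    rng = np.random.default_rng(config.seed)
    mix = np.asarray(config.archetype_mix, dtype=float)
    rec_parts, adm_parts, truth_parts, patient_rows = [], [], [], []
    width = max(4, len(str(config.n_patients)))
    for i in range(config.n_patients):
        mrn = f"P{i + 1:0{width}d}"
        arch = config.archetypes[int(rng.choice(len(config.archetypes), p=mix))]
        if isinstance(config.days_per_patient, tuple):
            lo, hi = config.days_per_patient
            n_days = int(rng.integers(lo, hi + 1))
        else:
            n_days = int(config.days_per_patient)
        admit = pd.Timestamp(config.start_date) + pd.Timedelta(days=int(rng.integers(0, 3)))
        age = float(np.clip(rng.normal(60, 15), 18, 100))
        sex = "male" if rng.random() < 0.55 else "female"
        rec, adm, truth = generate_patient_series(
            arch, n_days, admit, seed=int(rng.integers(0, 2**31 - 1)), mrn=mrn, age=age, sex=sex
        )
        rec_parts.append(rec)
        adm_parts.append(adm)
        truth_parts.append(truth)
        patient_rows.append({"mrn": mrn, "archetype": arch.name, "n_days": n_days})
    if not rec_parts:
        cohort = Cohort(
            recordings=_empty_recordings(),
            admissions=_empty_admissions(),
            truth=_empty_truth(),
            patients=pd.DataFrame(columns=["mrn", "archetype", "n_days"]),
        )
        return cohort
    cohort = Cohort(
        recordings=pd.concat(rec_parts, ignore_index=True),
        admissions=pd.concat(adm_parts, ignore_index=True),
        truth=pd.concat(truth_parts, ignore_index=True),
        patients=pd.DataFrame(patient_rows),
    )
    cohort = _drop_incomplete_days(cohort, config.frac_incomplete_days, int(rng.integers(0, 2**31 - 1)))
    cohort = inject_inconsistency(
        cohort, config.frac_inconsistent_patients, int(rng.integers(0, 2**31 - 1))
    )
    cohort = inject_overlap(cohort, config.frac_overlap_patients, int(rng.integers(0, 2**31 - 1)))
    return cohort.sort()


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write recordings.csv, admissions.csv and ground_truth.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "recordings": out / "recordings.csv",
        "admissions": out / "admissions.csv",
        "ground_truth": out / "ground_truth.csv",
    }
    cohort.sort()
    tio.write_recordings(cohort.recordings, paths["recordings"])
    tio.write_admissions(cohort.admissions, paths["admissions"])
    truth = cohort.truth[TRUTH_COLUMNS].copy()
    truth["timestamp"] = truth["timestamp"].dt.strftime(tio.TIMESTAMP_FORMAT)
    truth.to_csv(paths["ground_truth"], index=False)
    return paths


def read_cohort(out_dir: str | Path) -> Cohort:
    """Read back a written cohort (inverse of :func:`write_cohort`)."""
    out = Path(out_dir)
    recordings, rejected = tio.read_recordings(out / "recordings.csv")
    if len(rejected):
        raise ValueError("synthetic cohort should have no off-grid rows")
    admissions = tio.read_admissions(out / "admissions.csv")
    truth = pd.read_csv(out / "ground_truth.csv", dtype={"mrn": str}, keep_default_na=False)
    truth["timestamp"] = pd.to_datetime(truth["timestamp"], format="ISO8601")
    for col in ("is_overlap_injected", "is_out_of_window", "is_noise_flip"):
        truth[col] = truth[col].astype(str).str.lower().isin({"true", "1"})
    return Cohort(recordings=recordings, admissions=admissions, truth=truth).sort()
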