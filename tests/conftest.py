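import numpy as np
import pandas as pd
import pytest

from posturekit.synth import ArchetypeSpec, CohortConfig, generate_cohort

GRID = pd.Timedelta(seconds=15)


def make_series(groups, start="2019-03-01 00:00:00", mrn="P1", gap_after=()):
    """Build a GroupSeries frame from a list of group names.

    ``gap_after`` lists positions after which one grid slot is skipped.
    """
    ts = []
    t = pd.Timestamp(start)
    for i, _ in enumerate(groups):
        ts.append(t)
        t += GRID
        if i in set(gap_after):
            t += GRID
    return pd.DataFrame({"mrn": mrn, "timestamp": ts, "group": list(groups)})


def make_records(rows):
    """Build a recordings frame from (mrn, file, device, ts, posture) tuples."""
    df = pd.DataFrame(rows, columns=["mrn", "file_id", "device_serial", "timestamp", "posture"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_admissions(rows):
    """Build an admissions frame from (mrn, admit, discharge, age, sex) tuples."""
    df = pd.DataFrame(rows, columns=["mrn", "admit_time", "discharge_time", "age", "sex"])
    df["admit_time"] = pd.to_datetime(df["admit_time"])
    df["discharge_time"] = pd.to_datetime(df["discharge_time"])
    df["age"] = pd.array(df["age"], dtype="Float64")
    return df


def four_archetypes(noise_rate=0.01):
    """Four well-separated posture-habit archetypes (sedentary-lying,
    sedentary-reclined, active, unknown-dominant)."""
    return [
        ArchetypeSpec(
            "lying",
            {"Lying": 0.65, "Reclined": 0.2, "Upright": 0.1, "Unknown": 0.05},
            {"Lying": 0.85, "Reclined": 0.08, "Upright": 0.02, "Unknown": 0.05},
            mean_bout_len=25,
            noise_rate=noise_rate,
        ),
        ArchetypeSpec(
            "reclined",
            {"Lying": 0.12, "Reclined": 0.65, "Upright": 0.18, "Unknown": 0.05},
            {"Lying": 0.15, "Reclined": 0.75, "Upright": 0.05, "Unknown": 0.05},
            mean_bout_len=25,
            noise_rate=noise_rate,
        ),
        ArchetypeSpec(
            "active",
            {"Lying": 0.1, "Reclined": 0.3, "Upright": 0.55, "Unknown": 0.05},
            {"Lying": 0.5, "Reclined": 0.3, "Upright": 0.15, "Unknown": 0.05},
            mean_bout_len=6,
            noise_rate=noise_rate,
        ),
        ArchetypeSpec(
            "unknown",
            {"Lying": 0.15, "Reclined": 0.1, "Upright": 0.05, "Unknown": 0.7},
            {"Lying": 0.2, "Reclined": 0.05, "Upright": 0.05, "Unknown": 0.7},
            mean_bout_len=25,
            noise_rate=noise_rate,
        ),
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """10 patients x 2 days, no injected errors."""
    config = CohortConfig(
        n_patients=10,
        days_per_patient=2,
        archetypes=four_archetypes(),
        archetype_mix=[0.4, 0.3, 0.2, 0.1],
        seed=42,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def dirty_cohort():
    """20 patients x 3 days with every error type injected."""
    config = CohortConfig(
        n_patients=20,
        days_per_patient=3,
        archetypes=four_archetypes(),
        archetype_mix=[0.4, 0.3, 0.2, 0.1],
        frac_overlap_patients=0.2,
        frac_inconsistent_patients=0.2,
        frac_incomplete_days=0.1,
        seed=7,
    )
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
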