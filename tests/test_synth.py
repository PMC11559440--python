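import numpy as np
import pandas as pd
import pytest

from posturekit import stats
from posturekit.cleaning import apply_exclusions
from posturekit.groups import consolidate, smooth_majority_vote
from posturekit.synth import (
    ArchetypeSpec,
    Cohort,
    CohortConfig,
    ConfigurationError,
    generate_cohort,
    generate_patient_series,
    inject_inconsistency,
    inject_overlap,
    read_cohort,
    write_cohort,
)
from conftest import four_archetypes


def uniform_archetype(**kw):
    w = {"Lying": 0.25, "Reclined": 0.45, "Upright": 0.25, "Unknown": 0.05}
    night = {"Lying": 0.8, "Reclined": 0.1, "Upright": 0.05, "Unknown": 0.05}
    defaults = dict(mean_bout_len=10, noise_rate=0.0)
    defaults.update(kw)
    return ArchetypeSpec("mix", w, night, **defaults)


class TestValidation:
    def test_bad_weights(self):
        with pytest.raises(ConfigurationError):
            ArchetypeSpec("x", {"Lying": 0.5}, {"Lying": 1.0})
        with pytest.raises(ConfigurationError):
            ArchetypeSpec("x", {"Lying": 1.2, "Reclined": -0.2}, {"Lying": 1.0})

    def test_bad_bout_and_noise(self):
        w = {"Lying": 1.0}
        with pytest.raises(ConfigurationError):
            ArchetypeSpec("x", w, w, mean_bout_len=0.5)
        with pytest.raises(ConfigurationError):
            ArchetypeSpec("x", w, w, noise_rate=0.5)

    def test_bad_mix(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(2, 1, [uniform_archetype()], [0.5])

    def test_bad_fraction(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(2, 1, [uniform_archetype()], [1.0], frac_overlap_patients=1.5)

    def test_n_days(self):
        with pytest.raises(ConfigurationError):
            generate_patient_series(uniform_archetype(), 0, "2019-03-01", seed=0)


class TestPatientSeries:
    def test_degenerate_daytime_upright(self):
        arch = ArchetypeSpec(
            "upright",
            {"Upright": 1.0},
            {"Lying": 1.0},
            mean_bout_len=10,
            noise_rate=0.0,
        )
        rec, adm, truth = generate_patient_series(arch, 1, "2019-03-01", seed=0)
        series = consolidate(rec)
        hour = series["timestamp"].dt.hour
        daytime = series[(hour >= 7) & (hour < 19)]
        assert (daytime["group"] == "Upright").all()

    def test_nighttime_lying_weight_one(self):
        arch = ArchetypeSpec(
            "nt-lying", {"Upright": 1.0}, {"Lying": 1.0}, mean_bout_len=10, noise_rate=0.0
        )
        rec, adm, truth = generate_patient_series(arch, 1, "2019-03-01", seed=0)
        series = smooth_majority_vote(consolidate(rec))
        nt = stats.duration_stats(series, "NT")
        assert nt.loc["P0001", "Lying-NT"] == 12.0

    def test_grid_and_window(self):
        rec, adm, truth = generate_patient_series(uniform_archetype(), 2, "2019-03-05", seed=3)
        assert len(rec) == 2 * 5760
        assert (rec["timestamp"].dt.second % 15 == 0).all()
        assert rec["timestamp"].min() == adm.loc[0, "admit_time"]
        assert rec["timestamp"].max() < adm.loc[0, "discharge_time"]

    def test_daily_device_changeover(self):
        rec, _, _ = generate_patient_series(uniform_archetype(), 3, "2019-03-01", seed=3)
        per_day = rec.groupby(rec["timestamp"].dt.normalize())["device_serial"].nunique()
        assert (per_day == 1).all()
        assert rec["device_serial"].nunique() == 3

    def test_empirical_proportions_match_weights(self):
        arch = uniform_archetype()
        rec, _, truth = generate_patient_series(arch, 20, "2019-03-01", seed=11)
        hour = rec["timestamp"].dt.hour
        day_groups = truth.loc[((hour >= 7) & (hour < 19)).to_numpy(), "true_group"]
        props = day_groups.value_counts(normalize=True)
        for g, w in arch.daytime_group_weights.items():
            assert props.get(g, 0.0) == pytest.approx(w, abs=0.03)

    def test_consolidation_recovers_true_groups(self):
        # permutations at bout boundaries never change the classified group
        arch = uniform_archetype(permutation_rate=0.8, long_permutation_rate=0.2)
        rec, _, truth = generate_patient_series(arch, 2, "2019-03-01", seed=5)
        series = consolidate(rec)
        assert (series["group"].to_numpy() == truth["true_group"].to_numpy()).all()

    def test_multicode_permutations_emitted(self):
        arch = uniform_archetype(permutation_rate=0.8)
        rec, _, _ = generate_patient_series(arch, 1, "2019-03-01", seed=5)
        n_tokens = rec["posture"].str.split().str.len()
        assert (n_tokens > 1).any()


class TestNoise:
    def test_noise_flips_isolated_and_flagged(self):
        arch = uniform_archetype(noise_rate=0.05, mean_bout_len=30)
        rec, _, truth = generate_patient_series(arch, 2, "2019-03-01", seed=8)
        series = consolidate(rec)
        g = series["group"].to_numpy()
        flips = np.flatnonzero(truth["is_noise_flip"].to_numpy())
        assert len(flips) > 0
        for i in flips:
            assert g[i - 1] == g[i + 1] != g[i]

    def test_smoother_alteration_rate_matches_noise_rate(self):
        rate = 0.05
        arch = uniform_archetype(noise_rate=rate, mean_bout_len=30)
        rec, _, truth = generate_patient_series(arch, 3, "2019-03-01", seed=21)
        series = consolidate(rec)
        smoothed = smooth_majority_vote(series)
        altered = (series["group"] != smoothed["group"]).sum()
        n_interior = len(series) - 2
        assert n_interior >= 10_000
        se = np.sqrt(rate * (1 - rate) / n_interior)
        assert abs(altered / n_interior - rate) <= 3 * se


class TestInjections:
    def test_overlap_frac_zero_identity(self, small_cohort):
        before = small_cohort.recordings.copy()
        cohort = inject_overlap(small_cohort, 0.0, seed=0)
        pd.testing.assert_frame_equal(cohort.recordings, before)
        assert not cohort.truth["is_overlap_injected"].any()

    def test_overlap_requires_two_patients(self):
        cfg = CohortConfig(1, 1, [uniform_archetype()], [1.0], seed=0)
        cohort = generate_cohort(cfg)
        with pytest.raises(ConfigurationError):
            inject_overlap(cohort, 0.5, seed=0)

    def test_overlap_selected_fraction(self):
        cfg = CohortConfig(10, 1, [uniform_archetype()], [1.0], seed=1)
        cohort = inject_overlap(generate_cohort(cfg), 0.2, seed=2)
        injected = cohort.truth.loc[cohort.truth["is_overlap_injected"], "mrn"]
        assert injected.nunique() == 2

    def test_overlap_creates_collisions(self):
        cfg = CohortConfig(6, 1, [uniform_archetype()], [1.0], seed=3)
        cohort = inject_overlap(generate_cohort(cfg), 0.5, seed=4)
        truth, rec = cohort.truth, cohort.recordings
        flagged = truth.loc[truth["is_overlap_injected"], ["mrn", "timestamp"]]
        assert len(flagged) > 0
        counts = rec.groupby(["mrn", "timestamp"]).size()
        for key in pd.MultiIndex.from_frame(flagged):
            assert counts.loc[key] >= 2

    def test_inconsistency_frac_zero(self, small_cohort):
        cohort = inject_inconsistency(small_cohort, 0.0, seed=0)
        assert not cohort.truth["is_out_of_window"].any()

    def test_inconsistency_extension_count(self):
        cfg = CohortConfig(4, 1, [uniform_archetype()], [1.0], seed=5)
        cohort = generate_cohort(cfg)
        cohort = inject_inconsistency(
            cohort, 1.0, seed=6, min_extension_hours=4.0, max_extension_hours=4.0
        )
        truth = cohort.truth
        adm = cohort.admissions.set_index("mrn")
        for m, sub in truth[truth["is_out_of_window"]].groupby("mrn"):
            assert len(sub) == 960  # 4 h x 240 recordings/h
            after = (sub["timestamp"] > adm.loc[m, "discharge_time"]).all()
            before = (sub["timestamp"] < adm.loc[m, "admit_time"]).all()
            assert after or before

    def test_injected_rows_never_inside_window(self, dirty_cohort):
        truth = dirty_cohort.truth
        adm = dirty_cohort.admissions.set_index("mrn")
        oow = truth[truth["is_out_of_window"]]
        admit = oow["mrn"].map(adm["admit_time"])
        discharge = oow["mrn"].map(adm["discharge_time"])
        assert ((oow["timestamp"] < admit) | (oow["timestamp"] > discharge)).all()

    def test_every_flag_references_existing_recording(self, dirty_cohort):
        # truth is row-aligned with recordings
        assert len(dirty_cohort.truth) == len(dirty_cohort.recordings)
        same = dirty_cohort.truth[["mrn", "timestamp"]].eq(
            dirty_cohort.recordings[["mrn", "timestamp"]]
        )
        assert same.all().all()


class TestRoundTrip:
    def test_write_read_identity(self, tmp_path, dirty_cohort):
        write_cohort(dirty_cohort, tmp_path)
        back = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(back.recordings, dirty_cohort.recordings)
        pd.testing.assert_frame_equal(back.admissions, dirty_cohort.admissions)
        t_a = back.truth.reset_index(drop=True)
        t_b = dirty_cohort.truth.reset_index(drop=True)
        for col in ("is_overlap_injected", "is_out_of_window", "is_noise_flip", "true_group"):
            assert (t_a[col].to_numpy() == t_b[col].to_numpy()).all()

    def test_empty_cohort(self, tmp_path):
        cfg = CohortConfig(0, 1, [uniform_archetype()], [1.0], seed=0)
        cohort = generate_cohort(cfg)
        paths = write_cohort(cohort, tmp_path)
        for p in paths.values():
            assert p.exists()
            assert len(p.read_text().strip().splitlines()) == 1  # header only
        back = read_cohort(tmp_path)
        assert len(back.recordings) == 0

    def test_row_counts_complete_days(self, tmp_path):
        cfg = CohortConfig(2, 1, [uniform_archetype()], [1.0], seed=9)
        cohort = generate_cohort(cfg)
        paths = write_cohort(cohort, tmp_path)
        n_lines = len(paths["recordings"].read_text().strip().splitlines())
        assert n_lines == 2 * 5760 + 1  # 24 h x 240 rows/h per patient + header


class TestCleaningSoundness:
    def test_precision_and_recall_one(self, dirty_cohort):
        clean, _ = apply_exclusions(dirty_cohort.recordings, dirty_cohort.admissions)
        truth = dirty_cohort.truth
        rec = dirty_cohort.recordings
        collided = pd.MultiIndex.from_frame(
            truth.loc[truth["is_overlap_injected"], ["mrn", "timestamp"]]
        )
        rec_keys = pd.MultiIndex.from_frame(rec[["mrn", "timestamp"]])
        expected_removed = truth["is_out_of_window"].to_numpy() | rec_keys.isin(collided)
        kept = np.asarray(rec_keys.isin(pd.MultiIndex.from_frame(clean[["mrn", "timestamp"]])))
        removed = ~kept
        # recall 1: every expected row removed; precision 1: nothing else
        assert (removed[expected_removed]).all()
        assert not removed[~expected_removed].any()
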