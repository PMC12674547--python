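"""The synthetic cohort generator: schedules, day-level series, 1 Hz
session streams, and the fixture bundle round trip."""

import json

import numpy as np
import pytest

from fitfatigue.indicators import build_day_table, compute_external_load, compute_rmssd
from fitfatigue.io import read_day_table, read_session_streams
from fitfatigue.model import FfmParameters, evaluate_optimized
from fitfatigue.synthetic import (
    CohortConfig,
    InvalidConfigError,
    NoiseModel,
    SessionSpec,
    generate_schedule,
    simulate_cohort,
    simulate_day_series,
    simulate_session_streams,
    write_fixture_bundle,
)


class TestSchedule:
    def test_attendance_rounding_matches_planned_grid(self):
        # 77.8% of 36 planned sessions -> 28 attended
        cfg = CohortConfig(n_subjects=1, weeks=12, attendance_rate=0.778,
                           seed=5)
        (days,) = generate_schedule(cfg).values()
        assert days.size == 28
        assert days[0] == 1 and np.all(np.diff(days) > 0)

    def test_full_attendance_keeps_every_planned_day(self):
        cfg = CohortConfig(n_subjects=2, weeks=12, attendance_rate=1.0, seed=0)
        for days in generate_schedule(cfg).values():
            assert days.size == 36
            # 3/week grid re-anchored to day 1: offsets 0,2,4 then +7 weekly
            assert np.array_equal(
                days, np.array([7 * wk + off for wk in range(12)
                                for off in (1, 3, 5)]))

    def test_seed_reproducibility_and_variation(self):
        cfg = CohortConfig(n_subjects=3, attendance_rate=0.8, seed=11)
        a = generate_schedule(cfg)
        b = generate_schedule(cfg)
        c = generate_schedule(CohortConfig(n_subjects=3, attendance_rate=0.8,
                                           seed=12))
        assert all(np.array_equal(a[k], b[k]) for k in a)
        assert any(not np.array_equal(a[k], c[k]) for k in a)

    def test_invalid_attendance_rejected(self):
        with pytest.raises(InvalidConfigError):
            CohortConfig(attendance_rate=0.0)


class TestDaySeries:
    def test_zero_noise_equals_model_exactly(self, example_params):
        days = np.array([1, 3, 5, 10, 17])
        w = np.array([0.3, 0.8, 0.5, 1.0, 0.1])
        out = simulate_day_series(example_params, days, w,
                                  NoiseModel(day_level_sd=0.0), seed=1)
        expect = evaluate_optimized(example_params, days, w)
        assert np.array_equal(out.p_obs, expect)
        assert np.array_equal(out.p_true, expect)

    def test_symmetric_parameters_give_zero_signal(self):
        p = FfmParameters(a=1.0, tau_a=0.1, K_a=0.5, C1=0.2,
                          f=1.0, tau_f=0.1, K_f=0.5, C2=0.2)
        out = simulate_day_series(p, np.arange(1, 20), np.full(19, 0.7),
                                  NoiseModel(day_level_sd=0.0), seed=0)
        assert np.allclose(out.p_true, 0.0)

    def test_hand_worked_first_day(self):
        p = FfmParameters(a=1, tau_a=0.05, K_a=0.6, C1=0.4,
                          f=1, tau_f=0.2, K_f=0.3, C2=0.2)
        out = simulate_day_series(p, [1], [1.0], NoiseModel(0.0), seed=0)
        assert out.p_true[0] == pytest.approx(
            np.exp(-0.05) - np.exp(-0.2) + 0.3 + 0.2, abs=1e-12)

    def test_noise_is_seed_deterministic(self, example_params):
        args = (example_params, np.arange(1, 10), np.full(9, 0.5),
                NoiseModel(day_level_sd=0.1))
        a = simulate_day_series(*args, seed=4)
        b = simulate_day_series(*args, seed=4)
        assert np.array_equal(a.p_obs, b.p_obs)


class TestSessionStreams:
    spec = SessionSpec(subject_id="S01", day_index=1, rest_hr=60,
                       hr_max=200, duration_s=600)

    def test_final_minute_peak_hits_85pct_hrmax(self):
        df = simulate_session_streams(self.spec, seed=0)
        train = df[df.phase == "train"]
        assert train.hr_bpm.to_numpy()[-60:].max() == pytest.approx(170.0)

    def test_recovery_follows_exponential(self):
        df = simulate_session_streams(self.spec, seed=0)
        post = df[df.phase == "post5"].sort_values("second")
        s = post.second.to_numpy()
        expect = 60 + (170 - 60) * np.exp(-s / self.spec.tau_recovery_s)
        assert np.allclose(post.hr_bpm.to_numpy(), expect)

    def test_external_load_of_constant_session(self):
        spec = SessionSpec(subject_id="S01", day_index=1, mean_speed=2.0,
                           mean_resistance=3.0, duration_s=1800)
        df = simulate_session_streams(spec, seed=0)
        train = df[df.phase == "train"]
        assert compute_external_load(train.speed, train.resistance) == \
            pytest.approx(10800.0)

    def test_rmssd_matches_target_via_sqrt2_relation(self):
        # Monte-Carlo: mean RMSSD over seeds converges to the target
        target = 42.43
        spec = SessionSpec(subject_id="S01", day_index=1, duration_s=300,
                           target_rmssd_pre=target)
        vals = []
        for seed in range(100):
            df = simulate_session_streams(spec, seed=seed)
            vals.append(compute_rmssd(df[df.phase == "pre5"].rr_ms))
        assert np.mean(vals) == pytest.approx(target, rel=0.05)

    def test_zero_jitter_constant_hr_gives_zero_rmssd(self):
        spec = SessionSpec(subject_id="S01", day_index=1, duration_s=300,
                           target_rmssd_pre=0.0)
        df = simulate_session_streams(spec, NoiseModel(rr_jitter_sd=0.0),
                                      seed=3)
        assert compute_rmssd(df[df.phase == "pre5"].rr_ms) == 0.0

    def test_too_short_session_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_session_streams(
                SessionSpec(subject_id="S01", day_index=1, duration_s=60))


class TestFixtureBundle:
    def test_round_trip_and_row_count(self, tmp_path):
        cohort = simulate_cohort(CohortConfig(n_subjects=2, weeks=4, seed=3))
        paths = write_fixture_bundle(cohort, tmp_path, streams=False)
        table = read_day_table(paths["day_table"])
        assert len(table) == len(cohort.day_table)
        assert np.allclose(table["W_raw"], cohort.day_table["W_raw"])
        truth = json.loads(paths["ground_truth"].read_text())
        assert set(truth["subjects"]) == set(cohort.parameters)

    def test_streams_round_trip_into_day_table(self, tmp_path):
        cohort = simulate_cohort(CohortConfig(n_subjects=1, weeks=2, seed=9))
        # short sessions keep the fixture light
        from dataclasses import replace
        cohort.session_specs = {
            sid: [replace(spec, duration_s=300) for spec in specs]
            for sid, specs in cohort.session_specs.items()}
        paths = write_fixture_bundle(cohort, tmp_path, streams=True)
        records = read_session_streams(paths["session_streams"])
        assert len(records) == len(cohort.day_table)
        table = build_day_table(records)
        assert np.allclose(np.sort(table["W_raw"]),
                           np.sort(cohort.day_table["W_raw"] / 6.0))

    def test_empty_cohort_writes_valid_files(self, tmp_path):
        cohort = simulate_cohort(CohortConfig(n_subjects=1, weeks=1, seed=0))
        cohort.day_table = cohort.day_table.iloc[0:0]
        cohort.session_specs = {}
        paths = write_fixture_bundle(cohort, tmp_path, streams=True)
        assert read_day_table(paths["day_table"]).empty
        assert read_session_streams(paths["session_streams"]) == []

    def test_cohort_scale_matches_study_structure(self):
        cohort = simulate_cohort(CohortConfig(seed=1))
        counts = cohort.day_table.groupby("subject_id").size()
        assert len(counts) == 13
        assert (counts == 32).all()  # round(0.885 * 36)
        spans = cohort.day_table.groupby("subject_id")["day_index"].max()
        assert spans.between(71, 82).all()
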