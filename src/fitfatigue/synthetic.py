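"""Synthetic cohorts of wearable-style training data.

Generates everything downstream stages consume, without any study data:
attendance schedules on a 3-sessions-per-week grid, day-level performance
series from ground-truth fitness-fatigue parameters, and 1 Hz session
streams (ergometer speed/resistance, training and recovery heart rate, and
resting R-R interval windows) from which the load indicators are recomputed.

The default cohort emulates the structure of a 13-subject, 12-week
medium-intensity continuous-cycling study: 3 planned sessions per week,
30 minutes per session, a final-minute heart-rate target of 85 % of the
subject's maximum, and attendance around 88 %, giving 28-42 attended
sessions per subject over a 71-82 day period.

Noise is deliberately simple — additive Gaussian on the day-level
performance proxy and iid Gaussian jitter on R-R intervals — because both
have closed-form consequences that tests can check: zero day-level noise
makes the series equal the model exactly, and iid jitter of standard
deviation ``s`` on a constant-rate R-R window has expected RMSSD ``s * sqrt(2)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from io import StringIO
from pathlib import Path

import numpy as np
import pandas as pd

from .model import FfmParameters, evaluate_optimized

__all__ = [
    "CohortConfig",
    "SessionSpec",
    "NoiseModel",
    "DaySeries",
    "generate_schedule",
    "simulate_day_series",
    "simulate_session_streams",
    "simulate_cohort",
    "write_fixture_bundle",
    "draw_subject_parameters",
    "reference_cohort",
]

SESSIONS_PER_WEEK_OFFSETS = (1, 3, 5)  # Mon/Wed/Fri pattern within each week


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class CohortConfig:
    """Size, schedule density and attendance of a synthetic cohort."""

    n_subjects: int = 13
    weeks: int = 12
    sessions_per_week: int = 3
    attendance_rate: float = 0.885
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.weeks < 1 or self.sessions_per_week < 1:
            raise InvalidConfigError("counts must be >= 1")
        if not 0 < self.attendance_rate <= 1:
            raise InvalidConfigError(
                f"attendance_rate must lie in (0, 1], got {self.attendance_rate}")

    @property
    def planned_sessions(self) -> int:
        return self.weeks * self.sessions_per_week


@dataclass(frozen=True)
class SessionSpec:
    """Targets for one simulated session's streams."""

    subject_id: str
    day_index: int
    rest_hr: float = 62.0
    hr_max: float = 190.0
    target_rmssd_pre: float = 50.0
    target_rmssd_post: float = 20.0
    target_rmssd_post30: float = 40.0
    duration_s: int = 1800
    mean_speed: float = 2.0
    mean_resistance: float = 3.0
    tau_recovery_s: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.rest_hr < self.hr_max:
            raise InvalidConfigError("need 0 < rest_hr < hr_max")


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian noise magnitudes of the generator.

    ``day_level_sd`` perturbs the day-level performance proxy;
    ``rr_jitter_sd`` (ms) is the R-R jitter used when a session spec carries
    no RMSSD target (a target overrides it via ``sd = RMSSD / sqrt(2)``).
    """

    day_level_sd: float = 0.05
    rr_jitter_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.day_level_sd < 0 or self.rr_jitter_sd < 0:
            raise InvalidConfigError("noise standard deviations must be >= 0")


@dataclass
class DaySeries:
    """Day-level simulation output: observed and noise-free channels."""

    subject_id: str
    t: np.ndarray
    w: np.ndarray
    p_true: np.ndarray
    p_obs: np.ndarray


def _planned_days(weeks: int, sessions_per_week: int) -> np.ndarray:
    if sessions_per_week <= 3:
        offsets = SESSIONS_PER_WEEK_OFFSETS[:sessions_per_week]
    else:  # spread evenly across the week
        offsets = tuple(np.linspace(1, 7, sessions_per_week).round().astype(int))
    return np.array([7 * wk + off for wk in range(weeks) for off in offsets])


def generate_schedule(config: CohortConfig) -> dict[str, np.ndarray]:
    """Attendance schedules: per subject, the attended calendar days.

    Each subject attends ``round(attendance_rate * planned)`` sessions,
    drawn without replacement from the planned weekly grid (misses are
    idiosyncratic, so removal is uniform).  Day indices are re-anchored so
    the first attended session is day 1.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    planned = _planned_days(config.weeks, config.sessions_per_week)
    n_attend = int(np.floor(config.attendance_rate * planned.size + 0.5))
    out: dict[str, np.ndarray] = {}
    for i in range(config.n_subjects):
        days = np.sort(rng.choice(planned, size=n_attend, replace=False))
        out[f"S{i + 1:02d}"] = days - days[0] + 1
    return out


def simulate_day_series(params: FfmParameters, schedule, loads,
                        noise: NoiseModel = NoiseModel(),
                        seed: int | None = None,
                        subject_id: str = "S01") -> DaySeries:
    """Observed performance on each attended day: model value plus noise."""
    t = np.asarray(schedule, dtype=float)
    w = np.asarray(loads, dtype=float)
    if t.size != w.size:
        raise ValueError("schedule and loads must be equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("schedule days must be strictly increasing")
    p_true = evaluate_optimized(params, t, w)
    rng = np.random.default_rng(seed)
    p_obs = p_true + rng.normal(0.0, noise.day_level_sd, size=t.size)
    return DaySeries(subject_id=subject_id, t=t, w=w,
                     p_true=p_true, p_obs=p_obs)


def _rr_window(rng, hr_bpm: np.ndarray, jitter_sd: float) -> np.ndarray:
    rr = 60000.0 / hr_bpm
    return rr + rng.normal(0.0, jitter_sd, size=rr.size)


def simulate_session_streams(spec: SessionSpec,
                             noise: NoiseModel = NoiseModel(),
                             seed: int | None = None) -> pd.DataFrame:
    """One session's 1 Hz streams in the long CSV dialect.

    Phases: ``pre5`` (300 s seated rest), ``train`` (``duration_s`` of
    cycling, heart rate ramping from 60 % to exactly 85 % of ``hr_max`` in
    the final second), ``post5`` (300 s exponential heart-rate recovery with
    time constant ``tau_recovery_s``), ``post30`` (300 s seated rest
    30 minutes later).  Each rest-phase row carries one R-R interval whose
    jitter standard deviation is ``target RMSSD / sqrt(2)``, so the window's
    expected RMSSD matches its target.

    Columns: subject_id, day_index, phase, second, hr_bpm, rr_ms, speed,
    resistance — rr_ms only in rest phases, speed/resistance only in train.
    """
    if spec.duration_s < 120:
        raise InvalidConfigError(
            f"session must last >= 120 s for a final-minute window, "
            f"got {spec.duration_s}")
    rng = np.random.default_rng(seed)
    frames = []

    def _sd(target: float | None) -> float:
        return (noise.rr_jitter_sd if target is None
                else float(target) / np.sqrt(2.0))

    def rest_phase(name: str, hr: float, target_rmssd: float | None):
        hr_series = np.full(300, hr)
        rr = _rr_window(rng, hr_series, _sd(target_rmssd))
        frames.append(pd.DataFrame({
            "subject_id": spec.subject_id, "day_index": spec.day_index,
            "phase": name, "second": np.arange(1, 301),
            "hr_bpm": hr_series, "rr_ms": rr,
            "speed": np.nan, "resistance": np.nan,
        }))

    rest_phase("pre5", spec.rest_hr, spec.target_rmssd_pre)

    n = spec.duration_s
    hr_start, hr_peak = 0.60 * spec.hr_max, 0.85 * spec.hr_max
    hr_train = hr_start + (hr_peak - hr_start) * np.arange(n) / (n - 1)
    frames.append(pd.DataFrame({
        "subject_id": spec.subject_id, "day_index": spec.day_index,
        "phase": "train", "second": np.arange(1, n + 1),
        "hr_bpm": hr_train, "rr_ms": np.nan,
        "speed": np.full(n, spec.mean_speed),
        "resistance": np.full(n, spec.mean_resistance),
    }))

    s = np.arange(1, 301)
    hr_rec = spec.rest_hr + (hr_peak - spec.rest_hr) * np.exp(-s / spec.tau_recovery_s)
    rr_rec = _rr_window(rng, hr_rec, _sd(spec.target_rmssd_post))
    frames.append(pd.DataFrame({
        "subject_id": spec.subject_id, "day_index": spec.day_index,
        "phase": "post5", "second": s,
        "hr_bpm": hr_rec, "rr_ms": rr_rec,
        "speed": np.nan, "resistance": np.nan,
    }))

    rest_phase("post30", 1.03 * spec.rest_hr, spec.target_rmssd_post30)
    return pd.concat(frames, ignore_index=True)


def draw_subject_parameters(rng: np.random.Generator) -> FfmParameters:
    """Ground-truth parameters of one synthetic subject.

    Magnitudes follow the impulse-response training literature: adaptation
    decays over weeks (time constant 20-50 days), fatigue over days (2.5-10
    days), with order-one amplitudes and positive net load gain.  Reported
    in the ``K_f = 0``, ``C2 = 0`` convention.
    """
    return FfmParameters(
        a=rng.uniform(0.8, 1.5),
        tau_a=rng.uniform(0.02, 0.05),
        K_a=rng.uniform(0.3, 0.8),
        C1=rng.uniform(0.2, 0.6),
        f=rng.uniform(0.8, 1.5),
        tau_f=rng.uniform(0.10, 0.40),
        K_f=0.0,
        C2=0.0,
    )


@dataclass
class SyntheticCohort:
    """Everything one synthetic cohort produced."""

    config: CohortConfig
    noise: NoiseModel
    parameters: dict[str, FfmParameters]
    schedules: dict[str, np.ndarray]
    day_table: pd.DataFrame          # subject_id, day_index, session_index, W_raw
    day_series: dict[str, DaySeries]  # model-generated performance channels
    session_specs: dict[str, list[SessionSpec]]


def simulate_cohort(config: CohortConfig = CohortConfig(),
                    noise: NoiseModel = NoiseModel()) -> SyntheticCohort:
    """Full day-level cohort: schedules, loads, and model performance series.

    External load per day is ``duration * speed * resistance`` with mild
    day-to-day variation in speed and resistance; the normalized load fed to
    the ground-truth model is the per-subject 0.1-1 rescaling of ``W_raw``.
    Session stream specs (with per-subject resting heart rate, maximal heart
    rate and RMSSD baselines) are attached so callers can materialise 1 Hz
    streams on demand.
    """
    rng = np.random.default_rng(config.seed)
    schedules = generate_schedule(config)
    parameters: dict[str, FfmParameters] = {}
    day_series: dict[str, DaySeries] = {}
    session_specs: dict[str, list[SessionSpec]] = {}
    rows = []
    for sid, days in schedules.items():
        params = draw_subject_parameters(rng)
        parameters[sid] = params
        n = days.size
        speed = rng.normal(2.0, 0.15, size=n).clip(1.2, 3.0)
        resistance = rng.normal(3.0, 0.3, size=n).clip(1.5, 5.0)
        duration = 1800
        w_raw = duration * speed * resistance
        lo, hi = w_raw.min(), w_raw.max()
        w_norm = 0.1 + 0.9 * (w_raw - lo) / (hi - lo) if hi > lo else \
            np.full(n, 0.55)
        day_series[sid] = simulate_day_series(
            params, days, w_norm, noise,
            seed=int(rng.integers(2 ** 31)), subject_id=sid)

        rest_hr = float(rng.normal(62, 5))
        hr_max = float(rng.normal(190, 7))
        pre_base = float(np.clip(rng.normal(50, 10), 25, 90))
        specs = []
        for k, day in enumerate(days):
            pre = max(10.0, pre_base + float(rng.normal(0, 4)))
            post5 = pre * float(rng.uniform(0.30, 0.50))
            post30 = pre * float(rng.uniform(0.60, 0.90))
            specs.append(SessionSpec(
                subject_id=sid, day_index=int(day), rest_hr=rest_hr,
                hr_max=hr_max, target_rmssd_pre=pre, target_rmssd_post=post5,
                target_rmssd_post30=post30, duration_s=duration,
                mean_speed=float(speed[k]),
                mean_resistance=float(resistance[k]),
                # day-to-day autonomic state: recovery speed varies, which
                # is what the HRR indicators are meant to pick up
                tau_recovery_s=float(rng.uniform(40.0, 80.0))))
            rows.append({"subject_id": sid, "day_index": int(day),
                         "session_index": k + 1, "W_raw": float(w_raw[k])})
        session_specs[sid] = specs
    day_table = pd.DataFrame(
        rows, columns=["subject_id", "day_index", "session_index", "W_raw"])
    return SyntheticCohort(config=config, noise=noise, parameters=parameters,
                           schedules=schedules, day_table=day_table,
                           day_series=day_series, session_specs=session_specs)


def write_fixture_bundle(cohort: SyntheticCohort, out_dir,
                         streams: bool = True,
                         stream_seed: int = 0) -> dict[str, Path]:
    """Write a cohort as CSV/JSON files round-trippable by the I/O readers.

    Emits ``day_table.csv`` (raw day table), ``ground_truth.json``
    (per-subject parameters plus noise settings) and, unless ``streams`` is
    disabled, ``session_streams.csv`` in the long 1 Hz dialect.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["day_table"] = out / "day_table.csv"
    cohort.day_table.to_csv(paths["day_table"], index=False)

    truth = {
        "noise": asdict(cohort.noise),
        "config": asdict(cohort.config),
        "subjects": {sid: p.to_dict() for sid, p in cohort.parameters.items()},
    }
    paths["ground_truth"] = out / "ground_truth.json"
    paths["ground_truth"].write_text(json.dumps(truth, indent=2))

    if streams:
        rng = np.random.default_rng(stream_seed)
        frames = [
            simulate_session_streams(spec, cohort.noise,
                                     seed=int(rng.integers(2 ** 31)))
            for specs in cohort.session_specs.values() for spec in specs
        ]
        streams_df = (pd.concat(frames, ignore_index=True) if frames
                      else pd.DataFrame(columns=["subject_id", "day_index",
                                                 "phase", "second", "hr_bpm",
                                                 "rr_ms", "speed",
                                                 "resistance"]))
        paths["session_streams"] = out / "session_streams.csv"
        streams_df.to_csv(paths["session_streams"], index=False)
    return paths


_REFERENCE_COHORT_CSV = """\
subject,age,gender,bmi,activity_level,total_period_days,actual_sessions,attendance_pct
1,20,Female,22.08,Moderate,72,31,86.1
2,23,Female,19.75,High,79,42,100.0
3,25,Female,23.80,High,73,32,88.9
4,25,Female,21.23,Low,71,31,86.1
5,25,Male,25.86,Moderate,79,34,94.4
6,18,Female,18.31,High,72,29,80.6
7,19,Female,21.01,Moderate,78,32,88.9
8,19,Female,22.87,High,76,33,91.7
9,19,Female,19.96,Moderate,75,28,77.8
10,19,Male,23.15,High,75,30,83.3
11,28,Male,31.43,High,72,32,88.8
12,19,Male,27.41,High,75,33,91.7
13,21,Male,22.99,Low,75,33,91.7
"""


def reference_cohort() -> pd.DataFrame:
    """Characteristics of the published 13-subject cycling cohort this
    generator emulates: age, gender, BMI, activity level, training period,
    attended sessions, and attendance rate (percent of 36 planned sessions).
    """
    return pd.read_csv(StringIO(_REFERENCE_COHORT_CSV))
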