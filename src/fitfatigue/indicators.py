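"""External and internal training-load indicators from session-level streams.

External load ``W`` is the time integral (1 s rectangular sum) of the product
of ergometer speed and resistance level over a training session.  Internal
load is summarised three ways from heart-rate and R-R interval data:

* ``delta_hrr1`` (bpm): heart-rate recovery after one minute,
  ``HR_peak - HRR1``, where ``HR_peak`` is the peak of the final training
  minute and ``HRR1`` the mean heart rate over post-exercise seconds 1-60.
* ``hrr_pct`` (percent): ``100 * (HR_stage1 - HRR1) / HR_stage1`` with
  ``HR_stage1`` the mean over post-exercise seconds 1-15.
* ``tl_hrv`` (dimensionless): ``(Pre5 - Post5) / (Post30 - Post5)`` from the
  RMSSD of three 5-minute resting R-R windows (before training, immediately
  after, and 30 minutes after).

Each day's performance proxy is the ratio of normalized external load to
normalized internal load, with both sides mapped affinely onto [0.1, 1] so
the ratio is bounded in [0.1, 10] and can never divide by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SessionRecord",
    "HrrIndicators",
    "compute_external_load",
    "compute_rmssd",
    "compute_hrr_indicators",
    "compute_tl_hrv",
    "normalize_unit_interval",
    "compute_output_indicator",
    "enrich_day_table",
    "INDICATOR_COLUMNS",
]

#: day-table column name per internal-load indicator
INDICATOR_COLUMNS = ("hrr1_delta", "hrr_pct", "tl_hrv")


class InsufficientDataError(ValueError):
    """A series is too short for the requested statistic."""


class UndefinedIndicatorError(ArithmeticError):
    """An indicator's formula is undefined on this day (flag for exclusion)."""


class DegenerateScaleError(ValueError):
    """Normalization requested on a constant series."""


@dataclass
class SessionRecord:
    """Raw streams of one attended training day.

    All heart-rate series are 1 Hz in bpm; R-R windows are interval sequences
    in milliseconds recorded while seated at rest.
    """

    subject_id: str
    day_index: int
    speed_series: np.ndarray
    resistance_series: np.ndarray
    hr_final_minute: np.ndarray  # last 60 s of training
    hr_post_5min: np.ndarray     # 300 s immediately post-exercise
    rr_pre5: np.ndarray
    rr_post5: np.ndarray
    rr_post30: np.ndarray

    def __post_init__(self) -> None:
        for name in ("speed_series", "resistance_series", "hr_final_minute",
                     "hr_post_5min", "rr_pre5", "rr_post5", "rr_post30"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.speed_series.shape != self.resistance_series.shape:
            raise ValueError("speed and resistance series must be equal length")


@dataclass(frozen=True)
class HrrIndicators:
    hr_peak: float
    hrr1: float
    hr_stage1: float
    delta_hrr1: float
    hrr_pct: float


def compute_external_load(speed_series, resistance_series) -> float:
    """Rectangular 1 s integral of speed x resistance over a session."""
    s = np.asarray(speed_series, dtype=float)
    r = np.asarray(resistance_series, dtype=float)
    if s.shape != r.shape:
        raise ValueError(
            f"length mismatch: speed has {s.size} samples, resistance {r.size}")
    if s.size == 0:
        raise InsufficientDataError("empty session streams")
    return float(np.sum(s * r))


def compute_rmssd(rr_ms) -> float:
    """Root mean square of successive differences of R-R intervals (ms)."""
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise InsufficientDataError(
            f"RMSSD needs at least 2 intervals, got {rr.size}")
    d = np.diff(rr)
    return float(np.sqrt(np.mean(d * d)))


def compute_hrr_indicators(hr_final_minute, hr_post_5min) -> HrrIndicators:
    """Heart-rate-recovery summaries of one session.

    ``hr_final_minute`` must hold exactly the last 60 s of training;
    ``hr_post_5min`` at least the first 60 s after exercise stops.
    """
    hf = np.asarray(hr_final_minute, dtype=float)
    hp = np.asarray(hr_post_5min, dtype=float)
    if hf.size != 60:
        raise ValueError(f"final-minute series must be 60 samples, got {hf.size}")
    if hp.size < 60:
        raise InsufficientDataError(
            f"post-exercise series must cover >= 60 s, got {hp.size}")
    hr_peak = float(np.max(hf))
    hrr1 = float(np.mean(hp[:60]))
    hr_stage1 = float(np.mean(hp[:15]))
    if hr_stage1 == 0:
        raise UndefinedIndicatorError("HR_stage1 is zero")
    delta = hr_peak - hrr1
    pct = 100.0 * (hr_stage1 - hrr1) / hr_stage1
    return HrrIndicators(hr_peak, hrr1, hr_stage1, delta, pct)


def compute_tl_hrv(pre5_rmssd: float, post5_rmssd: float,
                   post30_rmssd: float) -> float:
    """HRV perturbation-and-recovery ratio ``(Pre5 - Post5) / (Post30 - Post5)``.

    Undefined when the 30-minute window has not recovered at all
    (``Post30 == Post5``); such days are flagged for exclusion upstream.
    """
    denom = post30_rmssd - post5_rmssd
    if denom == 0:
        raise UndefinedIndicatorError(
            "Post30 RMSSD equals Post5 RMSSD; ratio undefined")
    return float((pre5_rmssd - post5_rmssd) / denom)


def normalize_unit_interval(values, allow_constant: bool = False) -> np.ndarray:
    """Affine map of a series onto [0.1, 1]: min -> 0.1, max -> 1.0.

    The lower bound of 0.1 exists so that a normalized indicator can appear
    in a denominator without risk of division by zero.  A constant series has
    no scale; it is an error unless ``allow_constant`` is set, in which case
    every value maps to the midpoint 0.55.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("normalization needs at least 2 values")
    if not np.all(np.isfinite(v)):
        raise ValueError("normalization input must be finite")
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        if not allow_constant:
            raise DegenerateScaleError(
                "constant series has no scale to normalize")
        return np.full_like(v, 0.55)
    return 0.1 + 0.9 * (v - lo) / (hi - lo)


def compute_output_indicator(w_norm, i_norm):
    """Daily performance proxy ``P = W_norm / I_norm``, bounded in [0.1, 10]."""
    w = np.asarray(w_norm, dtype=float)
    i = np.asarray(i_norm, dtype=float)
    eps = 1e-12
    for name, x in (("w_norm", w), ("i_norm", i)):
        if np.any((x < 0.1 - eps) | (x > 1.0 + eps)):
            raise ValueError(f"{name} must lie in [0.1, 1]")
    out = w / i
    return float(out) if out.ndim == 0 else out


def summarize_session(record: SessionRecord) -> dict:
    """All day-level quantities of one session as a flat dict.

    An undefined TL_HRV day is passed through as NaN with ``tl_hrv_defined``
    False so the caller can drop and count it.
    """
    w = compute_external_load(record.speed_series, record.resistance_series)
    hrr = compute_hrr_indicators(record.hr_final_minute, record.hr_post_5min)
    pre5 = compute_rmssd(record.rr_pre5)
    post5 = compute_rmssd(record.rr_post5)
    post30 = compute_rmssd(record.rr_post30)
    try:
        tl = compute_tl_hrv(pre5, post5, post30)
        defined = True
    except UndefinedIndicatorError:
        tl, defined = float("nan"), False
    return {
        "subject_id": record.subject_id,
        "day_index": record.day_index,
        "W_raw": w,
        "hr_peak": hrr.hr_peak,
        "hrr1": hrr.hrr1,
        "hr_stage1": hrr.hr_stage1,
        "hrr1_delta": hrr.delta_hrr1,
        "hrr_pct": hrr.hrr_pct,
        "rmssd_pre5": pre5,
        "rmssd_post5": post5,
        "rmssd_post30": post30,
        "tl_hrv": tl,
        "tl_hrv_defined": defined,
    }


def build_day_table(records: list[SessionRecord]) -> pd.DataFrame:
    """Day table (one row per attended session) from raw session records."""
    rows = [summarize_session(r) for r in records]
    df = pd.DataFrame(rows).sort_values(["subject_id", "day_index"])
    df["session_index"] = df.groupby("subject_id").cumcount() + 1
    return df.reset_index(drop=True)


def enrich_day_table(day_table: pd.DataFrame,
                     learning_fraction: float | None = None) -> pd.DataFrame:
    """Append normalized columns and per-indicator performance proxies.

    Normalization is per subject and per column over that subject's full
    series, matching how each indicator series is scaled before the
    chronological split.  Because the test days then inform the scale, a
    leakage-free variant is available: with ``learning_fraction`` set, the
    affine map is computed on the first ``floor(fraction * n)`` days only and
    applied to all days (values may then fall outside [0.1, 1]).

    Adds ``w_norm``, ``<ind>_norm`` and ``p_obs_<ind>`` for every indicator
    column present among :data:`INDICATOR_COLUMNS`.
    """
    df = day_table.copy().sort_values(["subject_id", "day_index"])
    present = [c for c in INDICATOR_COLUMNS if c in df.columns]

    def _norm(series: pd.Series) -> pd.Series:
        v = series.to_numpy(dtype=float)
        if learning_fraction is None:
            ref = v
        else:
            n_learn = int(np.floor(learning_fraction * v.size))
            ref = v[:max(n_learn, 2)]
        lo, hi = np.nanmin(ref), np.nanmax(ref)
        if hi == lo:
            raise DegenerateScaleError(
                f"constant series for subject {series.name}")
        return pd.Series(0.1 + 0.9 * (v - lo) / (hi - lo), index=series.index)

    grouped = df.groupby("subject_id", group_keys=False)
    df["w_norm"] = grouped["W_raw"].apply(_norm)
    for col in present:
        df[f"{col}_norm"] = grouped[col].apply(_norm)
        df[f"p_obs_{col}"] = df["w_norm"] / df[f"{col}_norm"]
    return df.reset_index(drop=True)
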