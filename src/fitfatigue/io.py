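"""File formats and configuration: day tables, session streams, fit and
report JSON, and the surface-grid export for external 3D plotting.

All numbers written to JSON are rounded to 12 significant digits so that
repeated runs under the same seeds produce byte-identical reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import FitResult, SubjectSeries
from .indicators import INDICATOR_COLUMNS
from .model import FfmParameters, evaluate_optimized
from .indicators import SessionRecord

logger = logging.getLogger("fitfatigue")

__all__ = [
    "RunConfig",
    "read_day_table",
    "read_session_streams",
    "series_from_enriched",
    "write_fit_result",
    "read_fit_result",
    "write_json_report",
    "export_surface_grid",
]

DAY_TABLE_REQUIRED = ("subject_id", "day_index", "session_index", "W_raw")
STREAM_REQUIRED = ("subject_id", "day_index", "phase", "second",
                   "hr_bpm", "rr_ms", "speed", "resistance")
REST_PHASES = ("pre5", "post5", "post30")


class SchemaError(ValueError):
    pass


class IncompleteSessionError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline configuration; YAML-loadable, CLI flags override fields."""

    indicator: str = "hrr1_delta"
    split_fraction: float = 0.8
    n_starts: int = 32
    seed: int = 0
    day_level_sd: float = 0.05
    rr_jitter_sd: float = 5.0
    bonferroni_family: int = 3
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def read_day_table(path) -> pd.DataFrame:
    """Read and validate a day table CSV; sorted, duplicates rejected."""
    df = pd.read_csv(path)
    missing = [c for c in DAY_TABLE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"day table {path} missing column(s): {missing}")
    dup = df.duplicated(subset=["subject_id", "day_index"])
    if dup.any():
        raise SchemaError(
            f"duplicate (subject_id, day_index) rows: {int(dup.sum())}")
    sorted_df = df.sort_values(["subject_id", "day_index"],
                               kind="stable").reset_index(drop=True)
    if not sorted_df[["subject_id", "day_index"]].equals(
            df[["subject_id", "day_index"]].reset_index(drop=True)):
        logger.info("day table %s was not chronologically sorted; sorting", path)
    return sorted_df


def read_session_streams(path) -> list[SessionRecord]:
    """Parse the long 1 Hz stream CSV into one record per (subject, day)."""
    df = pd.read_csv(path)
    missing = [c for c in STREAM_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"stream file {path} missing column(s): {missing}")
    records = []
    for (sid, day), g in df.groupby(["subject_id", "day_index"], sort=True):
        phases = set(g["phase"])
        absent = [p for p in (*REST_PHASES, "train") if p not in phases]
        if absent:
            raise IncompleteSessionError(
                f"subject {sid} day {day}: missing phase(s) {absent}")
        g = g.sort_values(["phase", "second"])
        train = g[g.phase == "train"].sort_values("second")
        post5 = g[g.phase == "post5"].sort_values("second")
        if len(train) < 120:
            raise IncompleteSessionError(
                f"subject {sid} day {day}: train phase too short "
                f"({len(train)} s)")
        records.append(SessionRecord(
            subject_id=str(sid), day_index=int(day),
            speed_series=train["speed"].to_numpy(),
            resistance_series=train["resistance"].to_numpy(),
            hr_final_minute=train["hr_bpm"].to_numpy()[-60:],
            hr_post_5min=post5["hr_bpm"].to_numpy(),
            rr_pre5=g.loc[g.phase == "pre5", "rr_ms"].to_numpy(),
            rr_post5=post5["rr_ms"].to_numpy(),
            rr_post30=g.loc[g.phase == "post30", "rr_ms"].to_numpy(),
        ))
    return records


def series_from_enriched(df: pd.DataFrame, indicator: str
                         ) -> list[SubjectSeries]:
    """Per-subject (t, w, P) series for one indicator from an enriched table.

    Days whose indicator is undefined (NaN performance proxy) are dropped
    before any splitting, with a logged count.
    """
    if indicator not in INDICATOR_COLUMNS:
        raise ValueError(f"unknown indicator {indicator!r}; "
                         f"expected one of {INDICATOR_COLUMNS}")
    col = f"p_obs_{indicator}"
    if col not in df.columns:
        raise SchemaError(f"enriched day table lacks column {col}")
    out = []
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values("day_index")
        ok = g[col].notna() & g["w_norm"].notna()
        n_drop = int((~ok).sum())
        if n_drop:
            logger.info("subject %s: dropping %d undefined-indicator day(s)",
                        sid, n_drop)
        g = g[ok]
        out.append(SubjectSeries(
            subject_id=str(sid), indicator=indicator,
            t=g["day_index"].to_numpy(dtype=float),
            w=g["w_norm"].to_numpy(dtype=float),
            p_obs=g[col].to_numpy(dtype=float)))
    return out


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}") if np.isfinite(obj) else None
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return [_round_floats(x, sig) for x in obj.tolist()]
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(x, sig) for x in obj]
    return obj


def write_json_report(obj: dict, path) -> Path:
    """Serialize a report dict with floats at 12 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True)
                    + "\n")
    return path


def fit_result_path(out_dir, fit: FitResult) -> Path:
    return Path(out_dir) / f"fit_{fit.subject_id}_{fit.indicator}_{fit.model}.json"


def write_fit_result(fit: FitResult, out_dir) -> Path:
    path = fit_result_path(out_dir, fit)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_round_floats(fit.to_dict()), indent=2,
                               sort_keys=True) + "\n")
    return path


def read_fit_result(path) -> FitResult:
    return FitResult.from_dict(json.loads(Path(path).read_text()))


def export_surface_grid(fit: FitResult, w_grid, t_grid, path) -> pd.DataFrame:
    """Long-format (t, w, P) grid of a fitted optimized model for plotting."""
    if fit.model != "optimized":
        raise ValueError("surface export requires an optimized-model fit")
    w_grid = np.asarray(w_grid, dtype=float)
    t_grid = np.asarray(t_grid, dtype=float)
    if w_grid.size == 0 or t_grid.size == 0:
        raise ValueError("grids must be non-empty")
    tt, ww = np.meshgrid(t_grid, w_grid, indexing="ij")
    pp = evaluate_optimized(fit.parameters, tt, ww)
    df = pd.DataFrame({"t": tt.ravel(), "w": ww.ravel(), "P": pp.ravel()})
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)
    return df
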