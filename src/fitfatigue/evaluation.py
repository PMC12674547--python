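"""Fit metrics, prediction metrics, temporal-dependency analysis, and the
paired optimized-vs-original model comparison across subjects.

Goodness of fit on the learning split is reported as SSE, RMSE and R²; on
the held-out split as RMSE and MAPE.  Whether prediction error grows with
the horizon (days since the last learning session) is probed with a
Spearman rank correlation, exact by permutation enumeration at small n.
Per-subject metric pairs are compared with a Shapiro-Wilk-gated paired
t-test or Wilcoxon signed-rank test, Bonferroni-corrected over the family
of internal-load indicators.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PredictionMetrics",
    "ComparisonResult",
    "fit_metrics",
    "prediction_metrics",
    "temporal_dependency",
    "compare_models",
    "cohort_summary",
    "bonferroni",
]


class InsufficientDataError(ValueError):
    pass


def fit_metrics(observed, predicted):
    """Learning-set goodness of fit ``(SSE, RMSE, R²)``.

    ``R² = 1 - SSE / TSS`` about the observed mean; it is NaN (undefined)
    when the observations are constant, and may be negative for fits worse
    than the mean.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must be equal length")
    if o.size < 2:
        raise InsufficientDataError("need >= 2 observations")
    sse = float(np.sum((o - p) ** 2))
    rmse = float(np.sqrt(sse / o.size))
    tss = float(np.sum((o - o.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else float("nan")
    return sse, rmse, r2


@dataclass
class PredictionMetrics:
    """Held-out prediction accuracy with the per-day error breakdown."""

    rmse: float
    mape: float                      # percent
    ape: np.ndarray                  # per-day absolute percentage errors, %
    horizons: np.ndarray | None = None  # days since last learning session


def prediction_metrics(observed, predicted, test_days=None,
                       last_learning_day=None) -> PredictionMetrics:
    """RMSE and MAPE of held-out predictions.

    ``MAPE = (100 / n) * sum(|o - p| / |o|)``; observations of exactly zero
    are rejected (normalized performance proxies are >= 0.1 by construction,
    so this guards malformed input only).  Passing the test-day indices and
    the last learning day attaches prediction horizons for the temporal
    analysis.
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must be equal length")
    if o.size < 1:
        raise InsufficientDataError("need >= 1 observation")
    if np.any(o == 0):
        raise ZeroDivisionError("observed values must be nonzero for MAPE")
    sse = float(np.sum((o - p) ** 2))
    rmse = float(np.sqrt(sse / o.size))
    ape = 100.0 * np.abs(o - p) / np.abs(o)
    horizons = None
    if test_days is not None and last_learning_day is not None:
        horizons = np.asarray(test_days, dtype=float) - float(last_learning_day)
        if np.any(horizons <= 0):
            raise ValueError("test days must follow the last learning day")
    return PredictionMetrics(rmse=rmse, mape=float(ape.mean()),
                             ape=ape, horizons=horizons)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson_on_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        return float("nan")
    return float((rx @ ry) / denom)


def temporal_dependency(test_day_indices, last_learning_day, ape_vector,
                        exact_max_n: int = 8):
    """Spearman correlation between prediction horizon and absolute error.

    Horizons are days since the last learning session; a positive rho means
    error grows with temporal distance.  The two-sided p-value is exact —
    computed by enumerating all permutations of the error ranks — for
    ``n <= exact_max_n``, and uses the t approximation beyond that.

    Returns ``(rho, p)``.
    """
    days = np.asarray(test_day_indices, dtype=float)
    ape = np.asarray(ape_vector, dtype=float)
    if days.size != ape.size:
        raise ValueError("day and error vectors must be equal length")
    if days.size < 3:
        raise InsufficientDataError(
            f"temporal analysis needs >= 3 test days, got {days.size}")
    horizons = days - float(last_learning_day)
    if np.any(horizons <= 0):
        raise ValueError("all test days must follow the last learning day")

    rx, ry = _rank(horizons), _rank(ape)
    rho = _pearson_on_ranks(rx, ry)
    if np.isnan(rho):
        return rho, float("nan")
    n = days.size
    if n <= exact_max_n:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson_on_ranks(rx, np.asarray(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        p = float(stats.spearmanr(horizons, ape).pvalue)
    return rho, float(p)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value, capped at 1."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return min(1.0, float(p) * m)


@dataclass
class ComparisonResult:
    """Paired optimized-vs-original comparison of one metric across subjects."""

    metric: str
    differences: np.ndarray          # optimized - original, one per subject
    n: int
    normality_p: float | None
    test_used: str                   # "paired-t" | "wilcoxon" | "degenerate"
    statistic: float | None
    p_raw: float | None
    p_corrected: float | None
    family_size: int
    mean_difference: float
    direction: str                   # "optimized-higher" | "original-higher" | "tied"


def compare_models(metric_optimized, metric_original, family_size: int = 3,
                   metric: str = "", alpha_normality: float = 0.05
                   ) -> ComparisonResult:
    """Paired test of per-subject metric differences (optimized - original).

    Shapiro-Wilk gates the test choice: normally distributed differences go
    to a two-sided paired t-test, otherwise to a Wilcoxon signed-rank test
    (zeros discarded, ties average-ranked, exact for n <= 15 where
    attainable).  The raw p is Bonferroni-corrected over ``family_size``
    comparisons — by default the three internal-load indicators.
    """
    opt = np.asarray(metric_optimized, dtype=float)
    orig = np.asarray(metric_original, dtype=float)
    if opt.shape != orig.shape:
        raise ValueError("paired vectors must be equal length")
    keep = np.isfinite(opt) & np.isfinite(orig)
    d = (opt - orig)[keep]
    if d.size < 4:
        raise InsufficientDataError(
            f"need >= 4 defined pairs, got {d.size}")
    mean_d = float(d.mean())
    direction = ("optimized-higher" if mean_d > 0
                 else "original-higher" if mean_d < 0 else "tied")
    if np.all(d == 0):
        return ComparisonResult(metric=metric, differences=d, n=d.size,
                                normality_p=None, test_used="degenerate",
                                statistic=None, p_raw=None, p_corrected=None,
                                family_size=family_size,
                                mean_difference=0.0, direction="tied")

    normality_p = float(stats.shapiro(d).pvalue)
    if normality_p >= alpha_normality:
        res = stats.ttest_1samp(d, 0.0)
        test_used, statistic, p_raw = "paired-t", float(res.statistic), float(res.pvalue)
    else:
        nz = d[d != 0]  # classic zero-discard
        method = "exact" if nz.size <= 15 else "approx"
        try:
            res = stats.wilcoxon(nz, zero_method="wilcox", method=method)
        except ValueError:
            res = stats.wilcoxon(nz, zero_method="wilcox", method="approx")
        test_used, statistic, p_raw = "wilcoxon", float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        metric=metric, differences=d, n=d.size, normality_p=normality_p,
        test_used=test_used, statistic=statistic, p_raw=p_raw,
        p_corrected=bonferroni(p_raw, family_size), family_size=family_size,
        mean_difference=mean_d, direction=direction)


def cohort_summary(subject_table: pd.DataFrame) -> dict:
    """Cohort descriptive statistics from a per-subject characteristics table.

    Expects columns ``age``, ``gender``, ``bmi``, ``total_period_days``,
    ``actual_sessions``, ``attendance_pct``.  Means are arithmetic, standard
    deviations use the n-1 (sample) convention, and the total number of
    paired (load, indicator) observations is the sum of attended sessions.
    """
    if subject_table.empty:
        raise InsufficientDataError("empty subject table")
    df = subject_table
    out: dict = {"n_subjects": int(len(df))}
    for col in ("age", "bmi", "total_period_days", "actual_sessions",
                "attendance_pct"):
        if col in df.columns:
            v = df[col].to_numpy(dtype=float)
            out[f"{col}_mean"] = float(v.mean())
            out[f"{col}_sd"] = float(v.std(ddof=1)) if v.size > 1 else float("nan")
    if "gender" in df.columns:
        counts = df["gender"].str.lower().value_counts()
        total = counts.sum()
        out["female_pct"] = float(100.0 * counts.get("female", 0) / total)
        out["male_pct"] = float(100.0 * counts.get("male", 0) / total)
    if "actual_sessions" in df.columns:
        out["total_paired_observations"] = int(df["actual_sessions"].sum())
    return out
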