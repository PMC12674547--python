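"""End-to-end per-subject workflow: chronological split, model fitting,
held-out prediction, temporal-dependency analysis, and the across-subject
model comparison."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import (
    FitResult,
    SubjectSeries,
    fit_optimized,
    fit_original,
    predict,
    split_learning_test,
)
from .evaluation import (
    InsufficientDataError,
    compare_models,
    prediction_metrics,
    temporal_dependency,
)

logger = logging.getLogger("fitfatigue")

__all__ = ["SubjectEvaluation", "evaluate_subject", "run_models",
           "evaluation_table", "compare_from_evaluation"]


@dataclass
class SubjectEvaluation:
    """One (subject, indicator, model) row of the evaluation battery."""

    fit: FitResult
    test_rmse: float
    test_mape: float
    spearman_rho: float | None
    spearman_p: float | None
    n_test: int
    horizons: np.ndarray | None


def _subject_seed(base_seed: int | None, index: int) -> int:
    ss = np.random.SeedSequence([0 if base_seed is None else base_seed, index])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def evaluate_subject(series: SubjectSeries, model: str = "optimized",
                     split_fraction: float = 0.8, n_starts: int = 32,
                     random_state: int | None = None,
                     min_observations: int = 10) -> SubjectEvaluation:
    """Split one subject's series, fit the requested model on the learning
    part, and score predictions on the held-out part."""
    learn, test = split_learning_test(series, split_fraction)
    if model == "optimized":
        fit = fit_optimized(learn, n_starts=n_starts,
                            random_state=random_state,
                            min_observations=min_observations)
    elif model == "original":
        fit = fit_original(learn)
    else:
        raise ValueError(f"unknown model {model!r}")
    yhat = predict(fit, test)
    pm = prediction_metrics(test.p_obs, yhat, test_days=test.t,
                            last_learning_day=learn.t[-1])
    rho = p = None
    if len(test) >= 3:
        rho, p = temporal_dependency(test.t, learn.t[-1], pm.ape)
    return SubjectEvaluation(fit=fit, test_rmse=pm.rmse, test_mape=pm.mape,
                             spearman_rho=rho, spearman_p=p,
                             n_test=len(test), horizons=pm.horizons)


def run_models(series_list: list[SubjectSeries], models=("optimized", "original"),
               split_fraction: float = 0.8, n_starts: int = 32,
               seed: int | None = None,
               min_observations: int = 10) -> list[SubjectEvaluation]:
    """Evaluate every subject under every requested model.

    Each subject gets a deterministic child seed derived from ``seed`` and
    its position, so results do not depend on how many models are run."""
    out = []
    for i, series in enumerate(series_list):
        sub_seed = _subject_seed(seed, i)
        for model in models:
            try:
                out.append(evaluate_subject(
                    series, model=model, split_fraction=split_fraction,
                    n_starts=n_starts, random_state=sub_seed,
                    min_observations=min_observations))
            except (InsufficientDataError, ValueError) as exc:
                logger.warning("skipping subject %s model %s: %s",
                               series.subject_id, model, exc)
    return out


def evaluation_table(evaluations: list[SubjectEvaluation]) -> pd.DataFrame:
    """Flat per-(subject, indicator, model) metric table."""
    rows = []
    for ev in evaluations:
        rows.append({
            "subject_id": ev.fit.subject_id,
            "indicator": ev.fit.indicator,
            "model": ev.fit.model,
            "n_learning": ev.fit.n_learning,
            "n_test": ev.n_test,
            "sse": ev.fit.sse,
            "rmse": ev.fit.rmse,
            "r2": ev.fit.r2,
            "test_rmse": ev.test_rmse,
            "test_mape": ev.test_mape,
            "spearman_rho": ev.spearman_rho,
            "spearman_p": ev.spearman_p,
        })
    return pd.DataFrame(rows)


def compare_from_evaluation(eval_df: pd.DataFrame, metric: str,
                            indicator: str, family_size: int = 3):
    """Paired optimized-vs-original comparison of one metric for one
    indicator, subjects matched by id."""
    sub = eval_df[eval_df.indicator == indicator]
    wide = sub.pivot_table(index="subject_id", columns="model",
                           values=metric, aggfunc="first")
    if not {"optimized", "original"} <= set(wide.columns):
        raise ValueError("need both optimized and original rows to compare")
    wide = wide.dropna()
    return compare_models(wide["optimized"].to_numpy(),
                          wide["original"].to_numpy(),
                          family_size=family_size,
                          metric=f"{metric}[{indicator}]")
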