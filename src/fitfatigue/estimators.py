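"""Per-subject parameter estimation as scikit-learn style regressors.

Both models regress a daily performance proxy ``P`` on the feature matrix
``X = [t, w]`` (calendar day index, normalized external load):

* :class:`FitnessFatigueRegressor` fits the optimized fitness-fatigue model
  by bounded trust-region nonlinear least squares with seeded multistarts.
  Internally it works in the six-dimensional identifiable parametrisation
  ``(a, tau_a, f, tau_f, delta_K, delta_C)`` and reports eight coefficients
  under the convention ``K_f = 0``, ``C2 = 0``.
* :class:`OriginalLoadRegressor` fits the original load-proportional model
  ``P = delta_K * w`` in closed form (no intercept).

Estimators follow the scikit-learn contract (``get_params``/``set_params``,
fitted attributes with trailing underscores) so they compose with pipelines
and model-selection utilities; module-level ``fit_optimized`` /
``fit_original`` / ``predict`` are thin wrappers used by the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .model import (
    FfmParameters,
    IdentifiableSummary,
    OriginalParameters,
    canonicalize,
    evaluate_optimized,
    evaluate_original,
)

__all__ = [
    "FitnessFatigueRegressor",
    "OriginalLoadRegressor",
    "SubjectSeries",
    "FitResult",
    "split_learning_test",
    "fit_optimized",
    "fit_original",
    "predict",
    "EstimationFailureError",
]

#: default box bounds of the identifiable parameter vector
TAU_BOUNDS = (1e-4, 5.0)
LINEAR_BOUND = 100.0


class EstimationFailureError(RuntimeError):
    """No multistart of the least-squares solver converged."""


class TooFewObservationsError(ValueError):
    pass


def _validate_X_y(X, y=None):
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError(f"X must be (n, 2) columns [t, w], got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    if y is None:
        return X
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError("X and y have inconsistent lengths")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    return X, y


def _goodness(y, yhat):
    resid = y - yhat
    sse = float(resid @ resid)
    rmse = float(np.sqrt(sse / y.size))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / tss if tss > 0 else float("nan")
    return sse, rmse, r2


class FitnessFatigueRegressor(RegressorMixin, BaseEstimator):
    """Optimized fitness-fatigue model fitted by multistart bounded NLS.

    The sum of squared errors between observed performance and
    ``a e^{-tau_a t} - f e^{-tau_f t} + delta_K w + delta_C`` is minimised
    with scipy's trust-region-reflective solver inside box bounds, restarted
    from ``n_starts`` seeded draws (log-uniform decay rates, standard-normal
    linear coefficients) because the two-exponential landscape is multimodal.

    Parameters
    ----------
    n_starts : int, default 32
        Number of seeded multistarts; the lowest-SSE solution is kept.
    tau_bounds : (float, float), default (1e-4, 5.0)
        Box bounds of both decay rates, per day.
    linear_bound : float, default 100.0
        Symmetric bound on ``a``, ``f``, ``delta_K`` and ``delta_C``.
    min_observations : int, default 10
        Fitting floor; fewer learning observations raise an error.
    random_state : int or None
        Seed of the multistart draws.

    Attributes
    ----------
    params_ : FfmParameters
        Canonical fitted coefficients (``K_f = 0``, ``C2 = 0`` convention).
    summary_ : IdentifiableSummary
    sse_, rmse_, r2_ : float
        Learning-set goodness of fit.
    n_obs_ : int
    best_start_, n_converged_ : int
        Multistart diagnostics.
    """

    def __init__(self, n_starts: int = 32, tau_bounds=TAU_BOUNDS,
                 linear_bound: float = LINEAR_BOUND,
                 min_observations: int = 10, random_state: int | None = None):
        self.n_starts = n_starts
        self.tau_bounds = tau_bounds
        self.linear_bound = linear_bound
        self.min_observations = min_observations
        self.random_state = random_state

    # identifiable vector layout: [a, tau_a, f, tau_f, delta_K, delta_C]
    def _bounds(self):
        lo_tau, hi_tau = self.tau_bounds
        b = self.linear_bound
        lower = np.array([-b, lo_tau, -b, lo_tau, -b, -b])
        upper = np.array([b, hi_tau, b, hi_tau, b, b])
        return lower, upper

    def _draw_starts(self, seed_seq: np.random.SeedSequence):
        # one child seed per start: the draw sequence is a prefix of any
        # longer one, so raising n_starts can only lower the returned SSE
        lo_tau, hi_tau = self.tau_bounds
        starts = np.empty((self.n_starts, 6))
        for i, child in enumerate(seed_seq.spawn(self.n_starts)):
            r = np.random.default_rng(child)
            starts[i, [1, 3]] = np.exp(
                r.uniform(np.log(lo_tau), np.log(hi_tau), 2))
            starts[i, [0, 2, 4, 5]] = r.standard_normal(4)
        return np.clip(starts, *self._bounds())

    @staticmethod
    def _predict_theta(theta, t, w):
        a, tau_a, f, tau_f, dk, dc = theta
        return a * np.exp(-tau_a * t) - f * np.exp(-tau_f * t) + dk * w + dc

    def fit(self, X, y):
        X, y = _validate_X_y(X, y)
        if X.shape[0] < self.min_observations:
            raise TooFewObservationsError(
                f"need >= {self.min_observations} observations, got {X.shape[0]}")
        t, w = X[:, 0], X[:, 1]
        seed_seq = np.random.SeedSequence(self.random_state)
        bounds = self._bounds()

        def residuals(theta):
            return self._predict_theta(theta, t, w) - y

        best = None
        n_converged = 0
        for i, x0 in enumerate(self._draw_starts(seed_seq)):
            sol = least_squares(residuals, x0, bounds=bounds, method="trf",
                                max_nfev=5000)
            if not sol.success:
                continue
            n_converged += 1
            sse = 2.0 * sol.cost
            if best is None or sse < best[1]:
                best = (i, sse, sol.x)
        if best is None:
            raise EstimationFailureError(
                f"none of {self.n_starts} starts converged")

        idx, _, theta = best
        a, tau_a, f, tau_f, dk, dc = theta
        raw = FfmParameters(a=a, tau_a=tau_a, K_a=dk, C1=dc,
                            f=f, tau_f=tau_f, K_f=0.0, C2=0.0)
        self.params_, self.summary_ = canonicalize(raw)
        yhat = evaluate_optimized(self.params_, t, w)
        self.sse_, self.rmse_, self.r2_ = _goodness(y, yhat)
        self.n_obs_ = int(y.size)
        self.best_start_ = idx
        self.n_converged_ = n_converged
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = _validate_X_y(X)
        return evaluate_optimized(self.params_, X[:, 0], X[:, 1])


class OriginalLoadRegressor(RegressorMixin, BaseEstimator):
    """Original load-proportional model ``P = delta_K * w``.

    The single identifiable coefficient has the closed-form no-intercept
    least-squares solution ``delta_K = sum(P w) / sum(w^2)``; the day index
    column of ``X`` is accepted for interface parity but never used.
    """

    def fit(self, X, y):
        X, y = _validate_X_y(X, y)
        w = X[:, 1]
        sw2 = float(w @ w)
        if sw2 == 0:
            raise ValueError("all loads are zero; delta_K is unidentified")
        dk = float((y @ w) / sw2)
        self.params_ = OriginalParameters(K_a=dk, K_f=0.0)
        self.sse_, self.rmse_, self.r2_ = _goodness(y, dk * w)
        self.n_obs_ = int(y.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = _validate_X_y(X)
        return evaluate_original(self.params_, X[:, 1])


# ---------------------------------------------------------------------------
# series container and functional wrappers


@dataclass
class SubjectSeries:
    """One subject's chronologically ordered (t, w, P) observations for one
    internal-load indicator."""

    subject_id: str
    indicator: str
    t: np.ndarray
    w: np.ndarray
    p_obs: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.p_obs = np.asarray(self.p_obs, dtype=float)
        if not (self.t.size == self.w.size == self.p_obs.size):
            raise ValueError("t, w and p_obs must be equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("day indices must be strictly increasing")

    def __len__(self) -> int:
        return self.t.size

    @property
    def X(self) -> np.ndarray:
        return np.column_stack([self.t, self.w])


@dataclass
class FitResult:
    """Fitted parameters plus learning-set goodness of fit and diagnostics."""

    model: str                      # "optimized" | "original"
    subject_id: str
    indicator: str
    parameters: FfmParameters | OriginalParameters
    summary: IdentifiableSummary | None
    sse: float
    rmse: float
    r2: float
    n_learning: int
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        if self.model == "optimized":
            params = self.parameters.to_dict()
            params["canonical"] = True
        else:
            params = {"K_a": self.parameters.K_a, "K_f": self.parameters.K_f}
        return {
            "model": self.model,
            "subject_id": self.subject_id,
            "indicator": self.indicator,
            "parameters": params,
            "identifiable_summary": (self.summary.to_dict()
                                     if self.summary else None),
            "sse": self.sse,
            "rmse": self.rmse,
            "r2": self.r2,
            "n_learning": self.n_learning,
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        if d["model"] == "optimized":
            params = FfmParameters.from_dict(d["parameters"])
            summary = IdentifiableSummary(**d["identifiable_summary"])
        else:
            params = OriginalParameters(K_a=d["parameters"]["K_a"],
                                        K_f=d["parameters"].get("K_f", 0.0))
            summary = None
        return cls(model=d["model"], subject_id=d["subject_id"],
                   indicator=d["indicator"], parameters=params,
                   summary=summary, sse=d["sse"], rmse=d["rmse"],
                   r2=d["r2"], n_learning=d["n_learning"],
                   diagnostics=d.get("diagnostics", {}))


def split_learning_test(series: SubjectSeries, fraction: float = 0.8):
    """Chronological split: first ``floor(fraction * n)`` days learn, rest test."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    n = len(series)
    if n < 5:
        raise TooFewObservationsError(
            f"need >= 5 observations to split, got {n}")
    k = int(np.floor(fraction * n))
    learn = SubjectSeries(series.subject_id, series.indicator,
                          series.t[:k], series.w[:k], series.p_obs[:k])
    test = SubjectSeries(series.subject_id, series.indicator,
                         series.t[k:], series.w[k:], series.p_obs[k:])
    return learn, test


def fit_optimized(learning: SubjectSeries, n_starts: int = 32,
                  random_state: int | None = None,
                  min_observations: int = 10, **kwargs) -> FitResult:
    est = FitnessFatigueRegressor(n_starts=n_starts, random_state=random_state,
                                  min_observations=min_observations, **kwargs)
    est.fit(learning.X, learning.p_obs)
    return FitResult(
        model="optimized", subject_id=learning.subject_id,
        indicator=learning.indicator, parameters=est.params_,
        summary=est.summary_, sse=est.sse_, rmse=est.rmse_, r2=est.r2_,
        n_learning=est.n_obs_,
        diagnostics={"best_start": est.best_start_,
                     "n_converged": est.n_converged_,
                     "n_starts": est.n_starts},
    )


def fit_original(learning: SubjectSeries) -> FitResult:
    est = OriginalLoadRegressor().fit(learning.X, learning.p_obs)
    return FitResult(
        model="original", subject_id=learning.subject_id,
        indicator=learning.indicator, parameters=est.params_, summary=None,
        sse=est.sse_, rmse=est.rmse_, r2=est.r2_, n_learning=est.n_obs_,
    )


def predict(fit: FitResult, test: SubjectSeries) -> np.ndarray:
    """Evaluate a frozen fit on held-out days; no refitting."""
    if fit.model == "optimized":
        return evaluate_optimized(fit.parameters, test.t, test.w)
    return evaluate_original(fit.parameters, test.w)
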