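"""Closed-form fitness-fatigue model (FFM) of training performance.

Performance on day ``t`` under normalized external load ``w`` is modelled as
the difference between an adaptation and a fatigue component, each the sum of
a decaying exponential in calendar time, an instantaneous load gain, and an
integration constant::

    A(t, w) = a * exp(-tau_a * t) + K_a * w + C1
    F(t, w) = f * exp(-tau_f * t) + K_f * w + C2
    P(t, w) = A(t, w) - F(t, w)

The classic impulse-response variant (performance as a convolution of past
training impulses) is deliberately out of scope: here the exponentials decay
in a single global day index, with the first session at ``t = 1``.

Only the differences ``delta_K = K_a - K_f`` and ``delta_C = C1 - C2`` enter
``P``, so an eight-parameter vector is never identifiable from performance
data alone.  :class:`IdentifiableSummary` carries the six quantities the data
can determine; estimation is done in that reduced form and reported with the
convention ``K_f = 0``, ``C2 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np

__all__ = [
    "FfmParameters",
    "OriginalParameters",
    "IdentifiableSummary",
    "evaluate_optimized",
    "evaluate_components",
    "evaluate_original",
    "canonicalize",
]


class InvalidParametersError(ValueError):
    """Raised when model parameters violate their domain (e.g. tau <= 0)."""


@dataclass(frozen=True)
class FfmParameters:
    """The eight coefficients of the optimized fitness-fatigue model.

    Attributes
    ----------
    a, f : float
        Specificity (amplitude) coefficients of the adaptation and fatigue
        exponentials.  Dimensionless; sign unconstrained.
    tau_a, tau_f : float
        Decay rates of adaptation and fatigue, per day.  Must be > 0.
    K_a, K_f : float
        Gain per unit of normalized external load.
    C1, C2 : float
        Integration constants of the adaptation / fatigue general solutions.
    """

    a: float
    tau_a: float
    K_a: float
    C1: float
    f: float
    tau_f: float
    K_f: float
    C2: float

    def __post_init__(self) -> None:
        if not (self.tau_a > 0 and self.tau_f > 0):
            raise InvalidParametersError(
                f"decay rates must be positive, got tau_a={self.tau_a}, "
                f"tau_f={self.tau_f}"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FfmParameters":
        return cls(**{k: float(d[k]) for k in
                      ("a", "tau_a", "K_a", "C1", "f", "tau_f", "K_f", "C2")})


@dataclass(frozen=True)
class OriginalParameters:
    """Gain coefficients of the original (load-proportional) model
    ``P = K_a * w - K_f * w``.  Only ``K_a - K_f`` is identifiable."""

    K_a: float
    K_f: float = 0.0

    @property
    def delta_K(self) -> float:
        return self.K_a - self.K_f


@dataclass(frozen=True)
class IdentifiableSummary:
    """The six parameter combinations determined by performance data.

    Invariant under adding a common constant to (K_a, K_f) or to (C1, C2),
    the two transformations that leave every prediction unchanged.
    """

    a: float
    tau_a: float
    f: float
    tau_f: float
    delta_K: float
    delta_C: float

    @classmethod
    def from_parameters(cls, p: FfmParameters) -> "IdentifiableSummary":
        return cls(a=p.a, tau_a=p.tau_a, f=p.f, tau_f=p.tau_f,
                   delta_K=p.K_a - p.K_f, delta_C=p.C1 - p.C2)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_components(params: FfmParameters, t, w):
    """Return the adaptation and fatigue components ``(A, F)`` at (t, w).

    Broadcasts over array-valued ``t`` and ``w``.
    """
    t = np.asarray(t, dtype=float)
    w = np.asarray(w, dtype=float)
    A = params.a * np.exp(-params.tau_a * t) + params.K_a * w + params.C1
    F = params.f * np.exp(-params.tau_f * t) + params.K_f * w + params.C2
    return A, F


def evaluate_optimized(params: FfmParameters, t, w):
    """Performance ``P = A - F`` of the optimized model at day ``t``, load ``w``."""
    A, F = evaluate_components(params, t, w)
    return A - F


def evaluate_original(params: OriginalParameters, w):
    """Performance of the original model: ``P = (K_a - K_f) * w``, no time term."""
    w = np.asarray(w, dtype=float)
    return params.delta_K * w


def _is_canonical(p: FfmParameters) -> bool:
    if p.tau_f > p.tau_a:
        return True
    if p.tau_f == p.tau_a:
        return p.a >= p.f
    return False


def canonicalize(params: FfmParameters):
    """Resolve the exponential-label ambiguity of the model.

    The two exponential terms enter ``P`` as ``a e^{-tau_a t} - f e^{-tau_f t}``,
    so relabelling them with negated amplitudes leaves every prediction
    unchanged.  The canonical convention is ``tau_f >= tau_a`` (fatigue decays
    at least as fast as adaptation), with a ``tau`` tie broken toward
    ``a >= f`` where the relabelling can achieve it.

    Returns
    -------
    (FfmParameters, IdentifiableSummary)
        The canonical parameters and their identifiable summary.
    """
    if _is_canonical(params):
        out = params
    else:
        out = replace(
            params,
            a=-params.f, tau_a=params.tau_f,
            f=-params.a, tau_f=params.tau_a,
        )
        # The swap preserves P exactly; if it failed to reach the canonical
        # ordering (possible only on an exact tau tie), keep the original.
        if not _is_canonical(out):
            out = params
    return out, IdentifiableSummary.from_parameters(out)
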