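import numpy as np
import pytest

from fitfatigue.model import FfmParameters


@pytest.fixture
def example_params() -> FfmParameters:
    """Hand-checkable parameter set used in the worked evaluation examples."""
    return FfmParameters(a=1.0, tau_a=0.05, K_a=0.6, C1=0.4,
                         f=1.0, tau_f=0.2, K_f=0.3, C2=0.2)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)


@pytest.fixture
def toy_series():
    """Six (t, w, P) points from a known model, for brute-force oracles."""
    from fitfatigue.estimators import SubjectSeries
    from fitfatigue.model import evaluate_optimized

    params = FfmParameters(a=1.2, tau_a=0.04, K_a=0.5, C1=0.3,
                           f=1.0, tau_f=0.25, K_f=0.0, C2=0.0)
    t = np.array([1.0, 3.0, 8.0, 15.0, 22.0, 30.0])
    w = np.array([0.2, 0.9, 0.4, 1.0, 0.6, 0.1])
    p = evaluate_optimized(params, t, w)
    return SubjectSeries("toy", "hrr1_delta", t, w, p)
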