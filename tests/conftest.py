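import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oligoflux import KineticGroundTruth, LogisticFit
from oligoflux.synthetic import default_time_grid

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def canonical_fit() -> LogisticFit:
    """The study-conditions logistic parameters (a=50, kappa=0.02/min, c=0.3)."""
    return LogisticFit(
        a=50.0,
        kappa=0.02,
        c=0.3,
        lambda_=0.02 * np.sqrt(2 / 50.0),
        rss=0.0,
        r_squared=1.0,
        t_half=182.564,
        converged=True,
    )


@pytest.fixture
def canonical_truth() -> KineticGroundTruth:
    return KineticGroundTruth(a=50.0, kappa=0.02, c=0.3, noise_sd=0.02, seed=1)


@pytest.fixture
def t_grid() -> np.ndarray:
    return default_time_grid(2000.0, 2.0)


def make_fit(a, kappa, c=0.3) -> LogisticFit:
    from oligoflux.kinetics import _half_time_root, primary_nucleation_combination

    return LogisticFit(
        a=a,
        kappa=kappa,
        c=c,
        lambda_=primary_nucleation_combination(a, kappa),
        rss=0.0,
        r_squared=1.0,
        t_half=_half_time_root(a, kappa, c),
        converged=True,
    )


def draw_logistic_params(rng, n):
    """Random (a, kappa) draws in the normalized low-seed regime.

    a in [20, 1000] log-uniform keeps M(0) <= 5%, as for normalized traces;
    kappa in [0.002, 0.05]/min spans half-times of roughly 1-60 hours.
    """
    a = np.exp(rng.uniform(np.log(20.0), np.log(1000.0), size=n))
    kappa = np.exp(rng.uniform(np.log(0.002), np.log(0.05), size=n))
    return a, kappa
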