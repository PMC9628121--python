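import numpy as np
import pytest

from survbench.cohort import Cohort
from survbench.synthetic_registry import (
    CovariateSpec,
    OutcomeSpec,
    generate_covariates,
    generate_outcomes,
    make_prompt_like,
)


def make_linear_cohort(
    n: int,
    seed: int,
    beta=(0.5, -0.4, 0.3, 0.2),
    n_binary: int = 1,
    target_event_rate: float = 0.4,
    correlation: float = 0.2,
) -> Cohort:
    """Small Weibull proportional-hazards cohort with a purely linear
    predictor, for tests where a Cox model is correctly specified."""
    beta = np.asarray(beta, dtype=float)
    cov = CovariateSpec(
        n_binary=n_binary, n_continuous=len(beta) - n_binary, correlation=correlation
    )
    out = OutcomeSpec(
        weibull_shape=1.2,
        weibull_scale=4.0,
        linear_coefs=beta,
        target_event_rate=target_event_rate,
        horizon_tau=3.0,
    )
    X, col_types = generate_covariates(cov, n, seed)
    time, event = generate_outcomes(X, out, seed + 1)
    return Cohort(X=X, time=time, event=event, tau=3.0, col_types=col_types)


@pytest.fixture(scope="session")
def linear_cohort_spec():
    """The (covariate, outcome) specs matching :func:`make_linear_cohort`."""
    beta = np.array([0.5, -0.4, 0.3, 0.2])
    cov = CovariateSpec(n_binary=1, n_continuous=3, correlation=0.2)
    out = OutcomeSpec(
        weibull_shape=1.2,
        weibull_scale=4.0,
        linear_coefs=beta,
        target_event_rate=0.4,
        horizon_tau=3.0,
    )
    return cov, out


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-subject linear cohort shared by fast contract tests."""
    return make_linear_cohort(300, seed=101)


@pytest.fixture(scope="session")
def prompt_cohort():
    """One realization of the small-registry preset (calibration cached)."""
    return make_prompt_like(11)
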