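import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gutresponder import (
    MCMCConfig,
    ModelSpec,
    TrialSimConfig,
    fit_model,
    simulate_trial,
)
from gutresponder.diary import prepare_interval_series

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def crossover_trial():
    """A 10-subject crossover trial at the standard study conditions
    (periods 14/14/28/14 days, hierarchical scales 0.5/0.5/0.3/0.5)."""
    return simulate_trial(TrialSimConfig(n_subjects=10, seed=20240601))


@pytest.fixture(scope="session")
def crossover_series(crossover_trial):
    series, excluded = prepare_interval_series(crossover_trial.diaries)
    return series, excluded


@pytest.fixture(scope="session")
def fitted_individual_model(crossover_series):
    """Individual-effects Weibull fit at the desk-scale MCMC protocol
    (4 chains x 2,000 iterations, 1,000 burn-in).  Shared by the convergence,
    classification and WAIC tests to avoid refitting."""
    series, _ = crossover_series
    config = MCMCConfig(iterations=2000, chains=4, burn_in=1000, seed=7)
    return fit_model(series, ModelSpec(), config, strict=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
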