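"""Shared fixtures: synthetic study conditions and reduced-length scenario fits."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from humpback_assess import (
    CatchSeries,
    MCMCConfig,
    PriorSpec,
    run_mcmc,
)
from humpback_assess.scenarios import build_scenario
from humpback_assess.synthetic import (
    SyntheticTruth,
    generate_catches,
    synthetic_pool,
    true_trajectory,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: Reduced sampler settings for test fits: three dispersed chains, 10,000
#: post-burn iterations each, thin 10 -> 3,000 retained draws.  Posterior
#: medians under these settings agree with much longer runs well inside the
#: tolerances asserted anywhere in the suite.
REDUCED = MCMCConfig(n_burn=2_000, n_iter=10_000, thin=10, seed=42)


@pytest.fixture(scope="session")
def truth() -> SyntheticTruth:
    return SyntheticTruth()


@pytest.fixture(scope="session")
def catches(truth):
    return generate_catches(truth)


@pytest.fixture(scope="session")
def true_traj(truth, catches):
    return true_trajectory(truth, catches)


@pytest.fixture(scope="session")
def pool(truth):
    """One seeded observation set drawn from the synthetic truth."""
    return synthetic_pool(truth)


@pytest.fixture(scope="session")
def prior() -> PriorSpec:
    return PriorSpec()


@pytest.fixture(scope="session")
def zero_catches() -> CatchSeries:
    return CatchSeries(1901, np.zeros(10))


@pytest.fixture(scope="session")
def scenario_fits(pool, prior):
    """Reduced-length fits of the scenarios the structural checks compare."""
    fits = {}
    for i, name in enumerate(
        ("base_case", "updated", "sa1", "sa2", "sa3", "sa5")
    ):
        data, _ = build_scenario(name, pool)
        fits[name] = run_mcmc(data, prior, replace(REDUCED, seed=REDUCED.seed + i))
    return fits
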