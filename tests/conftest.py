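import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import migsphase as m

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def scenario():
    """One default simulated study shared across tests (seed 7)."""
    return m.default_scenario(7)


@pytest.fixture(scope="session")
def sim(scenario):
    """Library + truth drawn at the default study conditions (seed 7)."""
    params = m.SimulationParams(seed=7)
    library, truth = m.simulate_library(
        scenario.cassette, scenario.genes, params, precursor=scenario.precursor
    )
    return library, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
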