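import pytest

from popgrowth import GrowthSimConfig, derive_traits, simulate_trial


@pytest.fixture(scope="session")
def sim1():
    """Default simulated trial, seed 1: (derived trait table, truth)."""
    table, truth = simulate_trial(GrowthSimConfig(seed=1))
    return derive_traits(table), truth


@pytest.fixture(scope="session")
def traits1(sim1):
    return sim1[0]


@pytest.fixture(scope="session")
def truth1(sim1):
    return sim1[1]
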