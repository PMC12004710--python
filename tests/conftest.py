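import pytest

from nmibcgen.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def sim():
    """One default four-archetype cohort shared across module tests."""
    return simulate_cohort(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def cohort(sim):
    return sim.cohort


@pytest.fixture(scope="session")
def genome(sim):
    return sim.genome
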