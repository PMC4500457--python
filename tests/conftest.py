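import pytest

from linneangap import (
    SimulationConfig,
    margins_to_dataset,
    siluriformes_margins,
    simulate_records,
)


@pytest.fixture(scope="session")
def margins():
    return siluriformes_margins()


@pytest.fixture(scope="session")
def fixture_dataset(margins):
    """The survey-margins fixture expanded to record level (seed 1)."""
    return margins_to_dataset(margins, seed=1)


@pytest.fixture(scope="session")
def sim_dataset_truth():
    """One simulated survey with its generating truth (seed 7)."""
    return simulate_records(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def sim_dataset(sim_dataset_truth):
    return sim_dataset_truth[0]
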