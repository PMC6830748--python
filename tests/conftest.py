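import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from wildqg import SimulationConfig, simulate_population  # noqa: E402


def small_config(**kw):
    """A small but structurally complete population (~600 records)."""
    base = dict(n_founder_females=40, n_founder_males=30, n_years=20,
                carrying_capacity=40, seed=20)
    base.update(kw)
    return SimulationConfig(**base)


def tiny_config(**kw):
    """A very small population for fit-based unit tests (~250 records)."""
    base = dict(n_founder_females=25, n_founder_males=20, n_years=14,
                carrying_capacity=25, seed=21)
    base.update(kw)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_population(small_config())


@pytest.fixture(scope="session")
def tiny_dataset():
    return simulate_population(tiny_config())
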