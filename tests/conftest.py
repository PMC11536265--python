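import pytest

from nutrigrs.synthetic_cohort import (
    DEFAULT_PANEL, SimulationConfig, simulate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return DEFAULT_PANEL


@pytest.fixture(scope="session")
def sim_default():
    """One deterministically simulated default cohort, shared read-only."""
    return simulate_cohort(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=101)
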