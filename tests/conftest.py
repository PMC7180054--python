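import numpy as np
import pytest

from synaptrap import SimulationConfig


@pytest.fixture
def config() -> SimulationConfig:
    """Reference default configuration (full 40-min trajectory timing)."""
    return SimulationConfig()


@pytest.fixture
def short_config() -> SimulationConfig:
    """Reduced-span configuration for fast unit tests.

    Burn-in of 100 s still exceeds the default equilibration time
    1/k_off = 25 s, so steady-state checks remain valid.
    """
    return SimulationConfig(t_burn_in=100.0, t_baseline=100.0, t_post=200.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
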