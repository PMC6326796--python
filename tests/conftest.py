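import numpy as np
import pytest

from andgate import GateParameters, StochasticSettings, SyntheticConfig


@pytest.fixture
def params() -> GateParameters:
    """A generic, well-conditioned parameter set for unit tests."""
    return GateParameters(gamma=1.0, delta=1.0, nu=10.0, k=5.0, h=2.0, phi=1.0)


@pytest.fixture
def default_config() -> SyntheticConfig:
    """The generator's default in-silico experiment (illustrative regime)."""
    return SyntheticConfig(master_seed=0)


@pytest.fixture
def small_settings() -> StochasticSettings:
    return StochasticSettings(volume=3.0, t_end=5.0, n_cells=200, seed=11)
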