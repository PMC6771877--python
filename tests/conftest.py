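import numpy as np
import pytest

from isobarrier.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def config():
    """Small default simulation config used across module tests."""
    return SimulationConfig(seed=42)


@pytest.fixture
def overlap_config():
    return SimulationConfig(seed=42, range_overlap_fraction=0.5)
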