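import numpy as np
import pytest

from fibrinet.params import (
    ClotParameters,
    FiberGeometry,
    FibrinParameterSet,
    SimulationControls,
)


@pytest.fixture
def params():
    return FibrinParameterSet()


@pytest.fixture
def geometry():
    return FiberGeometry()


@pytest.fixture
def clot_params():
    return ClotParameters()


@pytest.fixture
def controls():
    return SimulationControls()


@pytest.fixture
def fast_controls():
    """Coarse continuation grid for tests that only need curve shape."""
    return SimulationControls(n_steps=60)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
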