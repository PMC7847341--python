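import numpy as np
import pytest

from geomhnn import (
    degrade,
    make_phantom,
    standard_degrade_spec,
    standard_phantom_spec,
)


@pytest.fixture(scope="session")
def phantom():
    """Clean standard brain-like phantom (220x200, seed 7)."""
    return make_phantom(standard_phantom_spec())


@pytest.fixture(scope="session")
def degraded(phantom):
    """Standard degradation: blur 1.5, contrast 0.4, noise 0.01, seed 11."""
    return degrade(phantom, standard_degrade_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
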