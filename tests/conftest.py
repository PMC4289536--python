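import numpy as np
import pytest
from hypothesis import settings

from streamide import Habitat, StageParams, derive_rates

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def habitat20():
    """The reference stream reach [0, 20] with a moderate quadrature grid."""
    return Habitat(0.0, 20.0, 401)


@pytest.fixture
def habitat_sym():
    """A short symmetric habitat [-1, 1]."""
    return Habitat(-1.0, 1.0, 201)


@pytest.fixture
def slow_stage():
    """Low-flow year: v=0.1, R=1.2 (the recurring example parameters)."""
    return StageParams(derive_rates(0.1, 1.0, 1.0), 1.2)


@pytest.fixture
def fast_stage():
    """High-flow year: v=1.0, R=1.5."""
    return StageParams(derive_rates(1.0, 1.0, 1.0), 1.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
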