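import numpy as np
import pytest

from venasl import (
    AcquisitionTiming,
    BloodProperties,
    KineticConstants,
    PhantomSpec,
    make_phantom,
)


@pytest.fixture(scope="session")
def blood():
    return BloodProperties()


@pytest.fixture(scope="session")
def consts():
    return KineticConstants()


@pytest.fixture(scope="session")
def multi_timing():
    return AcquisitionTiming()


@pytest.fixture(scope="session")
def single_timing():
    return AcquisitionTiming(plds=(1.2,), n_pairs=8)


@pytest.fixture(scope="session")
def small_phantom():
    """32^3 phantom shared across tests (read-only)."""
    return make_phantom(PhantomSpec(grid_shape=(32, 32, 32), seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
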