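import numpy as np
import pytest

from connforge import synth
from connforge.grid import ParcellationTable, VoxelGrid


@pytest.fixture(scope="session")
def phantom():
    """Default spherical-shell phantom (24^3, 8 ROIs)."""
    return synth.make_phantom(synth.PhantomSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def grid12():
    return VoxelGrid.isotropic((12, 12, 12))


@pytest.fixture
def small_table():
    return ParcellationTable(
        indices=np.array([1, 2, 3]),
        names=["roi-a", "roi-b", "roi-c"],
        hemispheres=["L", "R", "M"],
        cortical=np.array([True, True, False]),
    )
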