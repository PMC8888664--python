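import numpy as np
import pytest

from kqsm import (
    B0Vector,
    VoxelGrid,
    make_dipole_kernel,
    rotation_to_b0,
    smooth_random_phantom,
)


@pytest.fixture(scope="session")
def grid32():
    return VoxelGrid((32, 32, 32))


@pytest.fixture(scope="session")
def grid_small():
    return VoxelGrid((16, 16, 16))


@pytest.fixture(scope="session")
def b0_z():
    return B0Vector((0.0, 0.0, 1.0))


@pytest.fixture(scope="session")
def kernel32(grid32, b0_z):
    return make_dipole_kernel(grid32, b0_z)


@pytest.fixture(scope="session")
def three_orientations():
    return [rotation_to_b0(a) for a in (0.0, 25.0, 50.0)]


@pytest.fixture(scope="session")
def smooth_chi32(grid32):
    return smooth_random_phantom(grid32, seed=7, amplitude=0.1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
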