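import numpy as np
import pytest

from molforge import fixtures


@pytest.fixture
def benzene():
    return fixtures.make_molecule("benzene")


@pytest.fixture
def water():
    return fixtures.make_molecule("water")


@pytest.fixture
def ethane():
    return fixtures.make_molecule("ethane")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def abs_grid():
    """f(r) = |r| sampled on [-2, 2]^3 with 33 points per axis."""
    from molforge import ScalarGrid

    x = np.linspace(-2, 2, 33)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    step = x[1] - x[0]
    return ScalarGrid((-2, -2, -2), np.diag([step] * 3),
                      np.sqrt(X**2 + Y**2 + Z**2), "|r|")


def random_rigid_motion(rng):
    """A uniform random rotation matrix and a translation vector."""
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()
    t = rng.uniform(-5, 5, 3)
    return R, t
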