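import numpy as np
import pytest

from chromofold.chain import BeadChain, GeometryParams
from chromofold.fixtures import make_planted_matrix


@pytest.fixture
def geometry():
    return GeometryParams()


@pytest.fixture
def unit_pair():
    """Two unit-radius beads at touching distance along x."""
    return BeadChain.from_arrays(
        np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]), np.array([1.0, 1.0])
    )


@pytest.fixture
def planted_two_blocks():
    matrix, bounds = make_planted_matrix([5, 5], intra_density=10, inter_density=1, seed=0)
    return matrix, bounds


def random_chain(n, seed, radius_lo=2.0, radius_hi=6.0):
    """Seeded random chain used across property tests."""
    rng = np.random.default_rng(seed)
    radii = rng.uniform(radius_lo, radius_hi, size=n)
    pos = np.cumsum(rng.normal(scale=8.0, size=(n, 3)), axis=0)
    return BeadChain.from_arrays(pos, radii)
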