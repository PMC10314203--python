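import numpy as np
import pytest

from motinv import PointPattern


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def chiral5():
    """A generic (chiral) 5-point pattern used across mirror tests."""
    centers = np.array(
        [
            [-2.1, -1.3],
            [1.7, -2.2],
            [2.4, 1.1],
            [-0.6, 2.3],
            [0.4, -0.2],
        ]
    )
    return PointPattern(centers, R=0.4)


@pytest.fixture
def three_atom():
    """The 3-Gaussian pattern used by the grid-oracle comparisons."""
    return PointPattern([[-1.5, -0.5], [1.8, -0.9], [0.3, 1.9]], R=0.7)
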