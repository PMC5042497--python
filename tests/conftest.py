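import numpy as np
import pandas as pd
import pytest

from nichekit.homerange import UtilizationDistribution
from nichekit.io import LocationSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_locations(xy, animal_id="A1", species="sp", start="2006-01-01"):
    """LocationSet with one fix per day from an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    t = pd.date_range(start, periods=len(xy), freq="D")
    return LocationSet(animal_id=animal_id, species=species,
                       x=xy[:, 0], y=xy[:, 1], t=t)


def uniform_ud(shape=(40, 40), support=(slice(10, 30), slice(10, 30)),
               cell_size=1.0, origin=(0.0, 0.0)):
    """A uniform UD over a rectangular sub-region of the grid."""
    g = np.zeros(shape)
    g[support] = 1.0
    g /= g.sum() * cell_size ** 2
    return UtilizationDistribution(grid=g, cell_size=cell_size, origin=origin,
                                   bandwidth=(1.0, 1.0), n_points=1)


def gaussian_ud(sigma=1.0, cell_size=0.05, half_width=5.0, origin_shift=0.0):
    """UD grid filled from the exact bivariate normal density."""
    n = int(2 * half_width / cell_size)
    xs = -half_width + origin_shift + (np.arange(n) + 0.5) * cell_size
    ys = -half_width + origin_shift + (np.arange(n) + 0.5) * cell_size
    X, Y = np.meshgrid(xs, ys)
    g = np.exp(-0.5 * (((X - origin_shift) / sigma) ** 2
                       + ((Y - origin_shift) / sigma) ** 2))
    g /= g.sum() * cell_size ** 2
    return UtilizationDistribution(
        grid=g, cell_size=cell_size,
        origin=(-half_width + origin_shift, -half_width + origin_shift),
        bandwidth=(sigma, sigma), n_points=1)


@pytest.fixture
def bvn_points(rng):
    return rng.multivariate_normal([0.0, 0.0], np.eye(2), size=1000)
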