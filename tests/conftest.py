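import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from replihist.locio import NucleusMask, ellipse_mask


def make_table(coords, frame=0, channel="A"):
    """Localization DataFrame from an (n, 3) coordinate array."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    return pd.DataFrame(
        {
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "frame": np.broadcast_to(frame, n).astype(np.int64),
            "channel": np.broadcast_to(channel, n),
        }
    )


def square_mask(side_nm=10000.0, z_half=300.0):
    half = side_nm / 2.0
    poly = Polygon([(-half, -half), (half, -half), (half, half), (-half, half)])
    return NucleusMask(polygon=poly, z_min=-z_half, z_max=z_half)


@pytest.fixture
def nucleus_mask():
    return ellipse_mask(8000.0, 5000.0, 300.0)


@pytest.fixture
def box_mask():
    return square_mask()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
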