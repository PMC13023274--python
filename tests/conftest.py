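import numpy as np
import pandas as pd
import pytest

from catrange.types import FixSet


def make_fixset(xy, cat_id="cat", start="2019-06-15", freq="3min", mask=None):
    """FixSet from an (n, 2) coordinate array with a regular timestamp grid."""
    xy = np.asarray(xy, dtype=float)
    ts = pd.date_range(start, periods=len(xy), freq=freq)
    frame = pd.DataFrame({"timestamp": ts, "x": xy[:, 0], "y": xy[:, 1]})
    return FixSet(cat_id, frame, mask)


@pytest.fixture
def fixset_factory():
    return make_fixset


@pytest.fixture
def gaussian_cloud():
    """10,000 isotropic normal fixes (sigma = 20 m), no contamination."""
    rng = np.random.default_rng(2024)
    return make_fixset(rng.standard_normal((10_000, 2)) * 20.0, freq="s")
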