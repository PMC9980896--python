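import numpy as np
import pandas as pd
import pytest

from neomotion import MotionParams, RoiTable, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A small but fully-featured synthetic study configuration."""
    return SyntheticConfig(
        n_scans=8, n_frames=200, n_rois=8, tr_seconds=2.0, seed=7
    )


@pytest.fixture
def quiet_config():
    """No artifact or noise couplings: FD is independent of the signal."""
    return SyntheticConfig(
        n_scans=8, n_frames=200, n_rois=8, tr_seconds=2.0, seed=7,
        artifact_gain=0.0, dropout_gain=0.0,
    )


@pytest.fixture
def random_motion(rng):
    return MotionParams(rng.normal(0, 0.05, size=(150, 6)), frame_period=2.0)


@pytest.fixture
def square_roi_table():
    """Four ROIs: two mirrored homotopic pairs with easy distances."""
    df = pd.DataFrame(
        {
            "roi_id": [1, 2, 3, 4],
            "name": ["a_R", "a_L", "b_R", "b_L"],
            "hemi": ["R", "L", "R", "L"],
            "partner_id": [2, 1, 4, 3],
            "x_mm": [3.0, -3.0, 0.0, 0.0],
            "y_mm": [0.0, 0.0, 4.0, 4.0],
            "z_mm": [0.0, 0.0, 0.0, 0.0],
        }
    )
    return RoiTable(df)
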