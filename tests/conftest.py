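import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from monoquant.arraydens import ArrayLayout


@pytest.fixture
def small_layout():
    """4x4 membrane: two analytes in duplicate, POS/NEG/BLANK controls."""
    spot_map = {
        (0, 0): "POS", (0, 1): "POS", (0, 2): "NEG", (0, 3): "BLANK",
        (1, 0): "CCL2", (1, 1): "CCL2", (1, 2): "CCL5", (1, 3): "CCL5",
    }
    return ArrayLayout(grid_shape=(2, 4), spot_map=spot_map, spot_radius_px=4,
                       spacing_px=14, margin_px=10)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
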