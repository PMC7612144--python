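import numpy as np
import pytest

from cmquant import simulate
from cmquant.coloc import CellROI, ChannelImage


@pytest.fixture(scope="session")
def small_sted_fixture():
    """One small seeded two-channel field used by several test modules."""
    params = simulate.StedSimParams(image_size=256, n_filaments=6,
                                    n_puncta=40, true_frac_on=0.5, seed=42)
    return simulate.simulate_sted_pair(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_channel(rng):
    """Random 8-bit channel image."""
    pixels = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
    return ChannelImage(pixels, bit_depth=8, channel_label="VASH2",
                        pixel_size=20.0)


@pytest.fixture
def full_roi():
    return CellROI(np.ones((64, 64), dtype=bool), pixel_size=20.0)
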