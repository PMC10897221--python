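import numpy as np
import pytest

from stingquant.image import CellROI, ImageField


@pytest.fixture
def full_roi():
    """A rectangular ROI covering an entire 16x16 raster."""
    return CellROI(cell_id="cell", mask=np.ones((16, 16), dtype=bool))


@pytest.fixture
def random_two_channel():
    """Seeded random 16x16 two-channel image for property checks."""
    rng = np.random.default_rng(42)
    return ImageField(
        channels={
            "chA": rng.uniform(0, 100, (16, 16)),
            "chB": rng.uniform(0, 100, (16, 16)),
        }
    )
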