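import numpy as np
import pytest

import coflowrheo as cf


@pytest.fixture
def geometry():
    return cf.ChannelGeometry()


@pytest.fixture
def fluids():
    return cf.FluidPair()  # mu_R = 1 cP, mu_T = 2.95 cP


@pytest.fixture
def protocol():
    return cf.PumpProtocol(n_periods=1)


@pytest.fixture
def two_level_frame():
    """240 x 200 ROI: columns 0-129 dark (gray 40), 130-199 bright (200)."""
    frame = np.full((240, 200), 200, dtype=np.uint8)
    frame[:, :130] = 40
    return frame


def make_band_frame(width_px: float, frame_cols: int = 800, rows: int = 50,
                    start: int = 100, level: float = 200.0) -> np.ndarray:
    """Bright channel band of (possibly fractional) width on a dark frame;
    the fractional remainder becomes a partial-coverage edge pixel."""
    frame = np.zeros((rows, frame_cols))
    full = int(width_px)
    frame[:, start:start + full] = level
    frac = width_px - full
    if frac > 0:
        frame[:, start + full] = level * frac
    return frame


@pytest.fixture
def band_frame_factory():
    return make_band_frame
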