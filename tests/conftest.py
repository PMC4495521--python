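from datetime import datetime, timedelta, timezone

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from moundwatch import FrameRecord, MoundMask


@pytest.fixture
def textured_grid():
    """Smoothed random texture with plenty of gradient structure."""
    rng = np.random.default_rng(42)
    g = gaussian_filter(rng.uniform(0, 255, (48, 64)), 1.0)
    return np.clip(np.rint(g), 0, 255).astype(np.uint8)


@pytest.fixture
def flat_mask():
    """Full-frame mound mask for tests that do not exercise masking."""
    return MoundMask(np.ones((48, 64), dtype=bool))


def make_frame(intensity, seconds=0, mode="day"):
    return FrameRecord(
        timestamp=datetime(2010, 6, 1, 12, tzinfo=timezone.utc)
        + timedelta(seconds=seconds),
        sensor_mode=mode,
        intensity=np.asarray(intensity, dtype=np.uint8),
    )
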