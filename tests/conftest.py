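import numpy as np
import pytest

from thermotrack import ThermalFrame
from thermotrack.synth import generate_scenario
from thermotrack import scenarios


@pytest.fixture(scope="session")
def disjoint_video():
    """3 mice on separate lanes, 120 frames (session-cached)."""
    spec = scenarios.disjoint_scenario(n_mice=3, n_frames=120, seed=11)
    return generate_scenario(spec)


@pytest.fixture(scope="session")
def touching_video():
    """2 mice converging then walking in contact, 120 frames."""
    spec = scenarios.touching_pair_scenario(n_frames=120, seed=12)
    return generate_scenario(spec)


def two_level_frame(shape=(60, 60), bg=20.0, body=30.0, rect=None, index=0):
    """Noise-free frame with an optional warm rectangle (row0, row1, col0, col1)."""
    values = np.full(shape, bg)
    if rect is not None:
        r0, r1, c0, c1 = rect
        values[r0:r1, c0:c1] = body
    return ThermalFrame(values, index=index)


def ellipse_frame(shape=(80, 80), centre=(40.0, 40.0), half_axes=(20.0, 8.0),
                  theta=0.0, bg=20.0, offset=10.0, index=0):
    from thermotrack.synth import _ellipse_mask

    values = np.full(shape, bg)
    mask = _ellipse_mask(shape, np.asarray(centre), theta, half_axes)
    values[mask] = bg + offset
    return ThermalFrame(values, index=index), mask
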