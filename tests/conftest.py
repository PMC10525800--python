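import numpy as np
import pytest

from rehopredict import Bold4D, BrainMask
from rehopredict.synth import CohortConfig, RoiSpec, generate_bold_subject, interior_mask


@pytest.fixture
def full_mask_3():
    return BrainMask(np.ones((3, 3, 3)))


@pytest.fixture
def noise_bold_16():
    """Pure-noise 16^3 x 240 subject with its interior mask."""
    cfg = CohortConfig(grid_shape=(16, 16, 16), n_timepoints=240, rois=[])
    bold, _ = generate_bold_subject(cfg, 1, 7)
    return bold, interior_mask((16, 16, 16))


@pytest.fixture
def coherent_roi_bold():
    """16^3 x 240 subject with a coherence-0.9 box ROI at [4..8]^3."""
    roi = RoiSpec.box("a", (4, 4, 4), (8, 8, 8), coherence=0.9)
    cfg = CohortConfig(grid_shape=(16, 16, 16), n_timepoints=240, rois=[roi])
    bold, _ = generate_bold_subject(cfg, 1, 7)
    roi_mask = np.zeros((16, 16, 16), bool)
    roi_mask[4:9, 4:9, 4:9] = True
    return bold, interior_mask((16, 16, 16)), roi_mask


def sine_bold(freq_hz: float, tr: float = 2.0, t: int = 240) -> Bold4D:
    ts = np.sin(2 * np.pi * freq_hz * np.arange(t) * tr)
    data = np.tile(ts, (3, 3, 3, 1))
    return Bold4D(data, tr_seconds=tr)
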