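import numpy as np
import pytest

from mitoquant.imaging import CalibratedImage, PointROI


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_image():
    return CalibratedImage(np.full((64, 64), 7.0), pixel_size_um=0.1)


def poles_from_truth(truth):
    """Extract per-frame pole-pair PointROIs from an anaphase truth table."""
    return [
        (PointROI(r.pole1_x_px, r.pole1_y_px), PointROI(r.pole2_x_px, r.pole2_y_px))
        for r in truth.itertuples()
    ]
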