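import numpy as np
import pytest

from mpmtools import synthetic_fixtures as sf
from mpmtools.invasion import train_invasion_classifier


@pytest.fixture(scope="session")
def invasion_classifier():
    """One fixture-trained invasion classifier shared across the session."""
    data = sf.make_invasion_training_set(200, seed=1)
    return train_invasion_classifier(data, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def render_tubes(segments, size=256, sigma=2.0, tip_amp=0.8, tip_sigma=2.5):
    """Rasterise straight tube segments ((x0,y0),(x1,y1)) with Gaussian
    cross-section and bright endpoint blobs; peak-normalised."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    img = np.zeros((size, size))
    tips = []
    for (x0, y0), (x1, y1) in segments:
        px, py = xx - x0, yy - y0
        dx, dy = x1 - x0, y1 - y0
        L2 = dx * dx + dy * dy
        t = np.clip((px * dx + py * dy) / L2, 0.0, 1.0)
        d2 = (px - t * dx) ** 2 + (py - t * dy) ** 2
        img = np.maximum(img, np.exp(-d2 / (2 * sigma**2)))
        tips.extend([(x0, y0), (x1, y1)])
    for x, y in tips:
        img += tip_amp * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * tip_sigma**2))
    return img / img.max()
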