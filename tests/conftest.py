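import numpy as np
import pytest

from ndi import polarimetry as pol
from ndi import synthetic as syn


@pytest.fixture
def speckle():
    """Smooth random test image for registration/segmentation checks."""
    return syn.speckle_image(shape=(128, 128), seed=1)


@pytest.fixture
def uniform_scene():
    """Noiseless uniform polarized scene at r = 0.25, I = 600."""
    pset, truth = syn.make_polarized_scene(0.25, 600.0, shape=(48, 48), noise=False)
    return pset, truth


@pytest.fixture
def roi_grid():
    def make(shape, step=24, size=20):
        return [
            pol.Region.rectangle(r0, c0, size, size)
            for r0 in range(0, shape[0] - size + 1, step)
            for c0 in range(0, shape[1] - size + 1, step)
        ]

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(0)
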