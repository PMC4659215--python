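import numpy as np
import pytest

from specreg.preprocess import background_mask_from_intensity, integral_intensity_image
from specreg.segmentation import segment_spectral
from specreg.synthetic import make_scene, render_pair


@pytest.fixture(scope="session")
def small_scene():
    """A compact phantom used by unit tests across modules."""
    return make_scene(11, slide_shape=(200, 300), roi_shape=(60, 80), n_classes=5, blob_scale=15.0)


@pytest.fixture(scope="session")
def small_pair(small_scene):
    return render_pair(small_scene)


@pytest.fixture(scope="session")
def small_template(small_pair):
    """Segmented spectral template of the small phantom (k=8)."""
    cube, _ = small_pair
    mask = background_mask_from_intensity(integral_intensity_image(cube))
    return segment_spectral(cube, mask, 8, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
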