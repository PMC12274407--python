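import numpy as np
import pytest

from neurophen.segmentation import segment_granular_layer
from neurophen.stains import deconvolve, rgb_to_od
from neurophen.synthetic import (
    SceneParams,
    StraightCenterline,
    gen_cerebellum_image,
)


@pytest.fixture(scope="session")
def folium_scene():
    """Default semicircular-band scene, reused across the suite."""
    return gen_cerebellum_image(SceneParams(rng_seed=7))


@pytest.fixture(scope="session")
def folium_mask(folium_scene):
    nuclear, _, _ = deconvolve(rgb_to_od(folium_scene.rgb))
    return segment_granular_layer(nuclear)


@pytest.fixture(scope="session")
def straight_scene():
    """A straight horizontal band spanning the full image width."""
    px = 0.0007
    h_img, w_img = 900, 1600
    params = SceneParams(
        image_size_px=(h_img, w_img),
        pixel_size_mm_per_px=px,
        centerline=StraightCenterline(
            y0_mm=500 * px, x0_mm=0.0, x1_mm=w_img * px
        ),
        rng_seed=3,
    )
    return gen_cerebellum_image(params)


@pytest.fixture(scope="session")
def straight_nuclear(straight_scene):
    nuclear, _, _ = deconvolve(rgb_to_od(straight_scene.rgb))
    return nuclear


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
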