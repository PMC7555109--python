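import numpy as np
import pytest

from meatmsi.synthetic import SceneParams, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """A 96x120 scene with every tissue present."""
    params = SceneParams(image_height=96, image_width=120, n_fibers=18,
                         fat_fraction=0.10, seed=7)
    cube, truth, masks = generate_scene(params)
    return params, cube, truth, masks


@pytest.fixture(scope="session")
def reduced_ranges():
    """Default parameter ranges rescaled to a 96x120 frame."""
    ratio = (96 * 120) / (575 * 700)
    return {
        "fat_fraction": (0.0, 0.25),
        "perimysium_density": (0.25, 1.6),
        "n_fibers": (150 * ratio, 600 * ratio),
    }


@pytest.fixture(scope="session")
def small_base_params():
    return SceneParams(image_height=96, image_width=120, n_fibers=18)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
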