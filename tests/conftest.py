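import numpy as np
import pytest

from seedstand.synthetic_field import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def small_spec():
    """A fast-to-render reference-altitude scene: 1.2 m × 1.8 m, 8 seedlings."""
    return SceneSpec(
        altitude_m=15.0,
        image_size=(240, 360),
        n_seedlings=8,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_scene(small_spec):
    img, truth, mask = generate_scene(small_spec, return_mask=True)
    return img, truth, mask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
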