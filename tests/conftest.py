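import numpy as np
import pytest

from ulcerlab import SceneSpec, generate_scene


@pytest.fixture
def flat_scene():
    """A small piecewise-constant scene (no noise/illumination)."""
    spec = SceneSpec(size=(128, 128), seed=11, noise_sigma=0.0, illumination=0.0)
    return generate_scene(spec)


@pytest.fixture
def noisy_scene():
    """A small scene under the default noise/illumination settings."""
    return generate_scene(SceneSpec(size=(128, 128), seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
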