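import numpy as np
import pytest

from pestbox.geometry import ImageSize
from pestbox.synthetic import DetectorNoiseConfig, SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene_config():
    """A desk-scale scene world: same statistical structure, smaller canvas."""
    return SceneConfig(image_size=ImageSize(512, 480), seed=7)


@pytest.fixture
def isolated_scene_config():
    """Scenes without adhesion clusters, for exactness tests of the pipeline."""
    return SceneConfig(
        image_size=ImageSize(2095, 1944),
        adhesion_cluster_prob=0.0,
        p_missing_label=0.0,
        seed=11,
    )


@pytest.fixture
def perfect_detector():
    return DetectorNoiseConfig.perfect()
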