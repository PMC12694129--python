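import numpy as np
import pytest

from reefblocks.synthetic import SceneConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_scene_cfg():
    return SceneConfig(image_size=128, colony_count_range=(2, 5))


@pytest.fixture
def drift_matrix():
    """State-dependent transitions with strong non-identity drift."""
    return np.array([
        [0.80, 0.20, 0.00, 0.00],
        [0.00, 0.15, 0.85, 0.00],
        [0.00, 0.00, 0.10, 0.90],
        [0.00, 0.00, 0.00, 1.00],
    ])
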