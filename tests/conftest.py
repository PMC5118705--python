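import numpy as np
import pytest

from collagetex import CollageConfig, ImageScene, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene(rng):
    return ImageScene(rng.random((16, 16)) * 100.0, identifier="small")


@pytest.fixture
def full_mask():
    def _make(shape, group_id="g0"):
        return ROIMask(np.ones(shape, dtype=bool), group_id=group_id)

    return _make


@pytest.fixture
def tiny_config():
    return CollageConfig(window_radius=1, orientation_bins=16, hist_bins=10)
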