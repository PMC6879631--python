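import numpy as np
import pytest

from digitrack import synth
from digitrack.maps import AttentionMap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_raster():
    """(height, width) raster used by simulation-backed tests."""
    return (80, 96)


@pytest.fixture(scope="session")
def scenes(small_raster):
    return [synth.make_scene(small_raster, seed=100 + i, image_id=f"img{i}")
            for i in range(4)]


@pytest.fixture(scope="session")
def digit_cfg():
    # 30 Hz keeps simulated trajectories light; defaults are 60 Hz
    return synth.ExplorerConfig(mode="digit", sampling_rate_hz=30)


@pytest.fixture(scope="session")
def eye_cfg():
    return synth.ExplorerConfig(mode="eye")


def random_map(rng, raster, image_id="img", smooth=3.0):
    """Helper: a smooth random unity-normalized attention map."""
    from scipy.ndimage import gaussian_filter

    g = gaussian_filter(rng.random(raster), smooth, mode="reflect")
    g -= g.min()
    g /= g.max()
    return AttentionMap(g, image_id=image_id)
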