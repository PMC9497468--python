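import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_system():
    """Shared 64x64 Bendlet system with modest grids (fast)."""
    from bendseg.bendlet import build_bendlet_system

    return build_bendlet_system(
        (64, 64),
        n_scales=2,
        shear_grid=(-0.5, 0.0, 0.5),
        bend_grid=(0.0, 1 / 16, -1 / 16),
    )


@pytest.fixture(scope="session")
def smooth_image():
    from scipy import ndimage

    rng = np.random.default_rng(0)
    return ndimage.gaussian_filter(rng.random((64, 64)), 2.0)


@pytest.fixture(scope="session")
def disc_phantom_64():
    """64px two-phase disc: image, truth mask."""
    yy, xx = np.mgrid[0:64, 0:64]
    sdf = 14.0 - np.hypot(yy - 31.5, xx - 31.5)
    img = 0.25 + 0.5 * (0.5 * (1 + np.tanh(sdf)))
    return np.clip(img, 0, 1), sdf >= 0
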