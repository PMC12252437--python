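import numpy as np
import pytest
from scipy import ndimage as ndi

from petharm import VolumeGrid, make_phantom

SMALL_SHAPE = (40, 44, 38)
SPACING = (2.0, 2.0, 2.0)


@pytest.fixture(scope="session")
def small_phantom() -> VolumeGrid:
    """A desk-scale phantom shared by tests that only need structure."""
    return make_phantom(SMALL_SHAPE, SPACING)


@pytest.fixture(scope="session")
def smooth_volume() -> VolumeGrid:
    """A smooth random volume whose support stays >= 10 voxels from
    every boundary (so boundary padding never matters)."""
    rng = np.random.default_rng(42)
    margin = 10
    inner = tuple(n - 2 * margin for n in SMALL_SHAPE)
    bump = ndi.gaussian_filter(rng.random(inner), 2.0)
    # Hann taper per axis: smooth roll-off to exactly zero at the edge
    for ax, n in enumerate(inner):
        win = np.hanning(n + 2)[1:-1]
        bump *= win.reshape([-1 if a == ax else 1 for a in range(3)])
    data = np.zeros(SMALL_SHAPE)
    data[margin:-margin, margin:-margin, margin:-margin] = bump
    return VolumeGrid(data, SPACING)


@pytest.fixture(scope="session")
def blob_volume() -> VolumeGrid:
    """Sum of analytic Gaussian blobs on a 1 mm lattice, support well
    inside the field.  Band-limited enough that sampled-kernel effects
    stay below the tolerances of the convolution-algebra tests (FWHM
    below ~2 voxels deviates measurably; see the methods note)."""
    shape = (48, 48, 48)
    idx = np.indices(shape, dtype=np.float64)
    data = np.zeros(shape)
    blobs = [
        ((23.5, 23.5, 23.5), 3.0, 1.0),
        ((20.5, 26.5, 22.5), 3.5, 0.6),
        ((27.5, 21.5, 25.5), 4.0, 0.4),
    ]
    for center, sigma, amp in blobs:
        r2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
        data += amp * np.exp(-r2 / (2.0 * sigma**2))
    return VolumeGrid(data, (1.0, 1.0, 1.0))


def random_smooth_pair(seed: int, shape=(16, 16, 16)):
    """Two smooth random arrays in [0, 1]-ish range for SSIM oracle tests."""
    rng = np.random.default_rng(seed)
    x = ndi.gaussian_filter(rng.random(shape), 1.0)
    y = ndi.gaussian_filter(rng.random(shape), 1.0)
    return x, y
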