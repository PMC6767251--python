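import numpy as np
import pytest

from silact.geometry import ImageGrid, ScanGeometry
from silact.phantoms import rasterize_ellipses, EllipseSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_grid():
    return ImageGrid(16, 16, 1.0)


@pytest.fixture
def small_geometry():
    return ScanGeometry("parallel", n_views=8, n_bins=24, bin_size=1.0)


@pytest.fixture
def tiny_grid():
    """4x4 grid paired with a well-conditioned 8-view system."""
    return ImageGrid(4, 4, 1.0)


@pytest.fixture
def tiny_geometry():
    return ScanGeometry("parallel", n_views=8, n_bins=12, bin_size=0.5)


@pytest.fixture
def disk_image():
    """Centred uniform disk rasterised with anti-aliasing on a 128 grid."""
    grid = ImageGrid(128, 128, 1.0)
    img = rasterize_ellipses(
        [EllipseSpec(center=(0.0, 0.0), semi_axes=(40.0, 40.0), intensity=1.0)],
        grid, supersample=4)
    return grid, img
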