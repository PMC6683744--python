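import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracle_geometry

import cortexmetrics as cm  # noqa: E402


def rasterize_mask(verts_yx: np.ndarray, size: int) -> "cm.LabelImage":
    """Rasterize a polygon (y, x vertices in px, origin at image center)."""
    from skimage.draw import polygon as draw_polygon

    img = np.zeros((size, size), dtype=np.int32)
    rr, cc = draw_polygon(verts_yx[:, 0] + size / 2, verts_yx[:, 1] + size / 2,
                          shape=img.shape)
    img[rr, cc] = 1
    return cm.LabelImage(img, pixel_size_xy=1.0, border_excluded=False)


def rasterize_disk(radius: int) -> "cm.LabelImage":
    from skimage.draw import disk as draw_disk

    size = 2 * radius + 20
    img = np.zeros((size, size), dtype=np.int32)
    rr, cc = draw_disk((size / 2, size / 2), radius)
    img[rr, cc] = 1
    return cm.LabelImage(img, pixel_size_xy=1.0, border_excluded=False)


@pytest.fixture(scope="session")
def small_config() -> "cm.PipelineConfig":
    """Config with a fixed marker radius for fast, deterministic runs."""
    return cm.PipelineConfig(marker_radius=20)


@pytest.fixture(scope="session")
def hex_scene():
    """Small noiseless hexagonal network scene with truth."""
    return cm.make_network_frame("hexagonal", n_cells=(3, 3), seed=1)


@pytest.fixture(scope="session")
def hex_labels(hex_scene, small_config):
    grid, _ = hex_scene
    return cm.segment_openings(grid, small_config)
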