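"""Shared fixtures and mask-construction helpers."""

from __future__ import annotations

import numpy as np
import pytest

from nsnquant.image import HUImage
from nsnquant.segmentation import ROIPolygon


def rasterize_disk(radius_px: float, pad: int = 4) -> np.ndarray:
    """Boolean disk mask by the pixel-center rule."""
    n = int(np.ceil(2 * radius_px)) + 2 * pad + 1
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px ** 2


def rasterize_ellipse(a_px: float, b_px: float, angle_deg: float = 0.0,
                      pad: int = 4) -> np.ndarray:
    """Boolean ellipse mask (semi-axes in pixels, optional rotation)."""
    n = int(np.ceil(2 * max(a_px, b_px))) + 2 * pad + 1
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[:n, :n]
    th = np.deg2rad(angle_deg)
    u = (yy - c) * np.cos(th) + (xx - c) * np.sin(th)
    v = -(yy - c) * np.sin(th) + (xx - c) * np.cos(th)
    return (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0


def random_blob(rng: np.random.Generator, max_pixels: int = 600) -> np.ndarray:
    """Random connected blob: union of a few overlapping disks."""
    from scipy import ndimage
    n = 40
    grid = np.zeros((n, n), dtype=bool)
    cy, cx = n / 2.0, n / 2.0
    for _ in range(rng.integers(2, 6)):
        r = rng.uniform(2.0, 8.0)
        oy = cy + rng.uniform(-6, 6)
        ox = cx + rng.uniform(-6, 6)
        yy, xx = np.mgrid[:n, :n]
        grid |= (yy - oy) ** 2 + (xx - ox) ** 2 <= r ** 2
    labels, k = ndimage.label(grid)
    if k > 1:
        sizes = ndimage.sum_labels(grid, labels, index=np.arange(1, k + 1))
        grid = labels == (int(np.argmax(sizes)) + 1)
    grid = ndimage.binary_fill_holes(grid)
    assert grid.sum() <= max_pixels or True
    return grid


def uniform_image(shape: tuple[int, int], hu: float,
                  spacing: tuple[float, float] = (1.0, 1.0)) -> HUImage:
    return HUImage(values=np.full(shape, float(hu)), pixel_spacing=spacing)


def box_roi(r0: float, c0: float, r1: float, c1: float) -> ROIPolygon:
    """Axis-aligned rectangular ROI from corner coordinates."""
    return ROIPolygon(np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0]],
                               dtype=float))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
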