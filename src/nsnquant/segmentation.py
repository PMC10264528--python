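"""Polygonal-ROI, fixed-threshold nodule segmentation.

The workflow mirrors how nonsolid nodules are segmented interactively on a
lung-window CT slice: the reader outlines the nodule with a polygonal
region of interest, a fixed attenuation threshold (default -800 HU,
inclusive) separates ground-glass tissue from aerated parenchyma inside the
ROI, the largest 8-connected component is retained and its interior holes
are filled.  When a nodule spans several slices, the slice with the largest
segmented cross-sectional area is the one analysed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point, Polygon

from .errors import RoiError, SegmentationError
from .image import HUImage

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_HU = -800.0


@dataclass(frozen=True)
class ROIPolygon:
    """A simple (non-self-intersecting) polygon in pixel coordinates.

    Vertices are ``(row, col)`` points; the polygon is implicitly closed.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self):
        verts = np.asarray(self.vertices, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2:
            raise RoiError(f"vertices must be an (n, 2) array, got {verts.shape}")
        # drop an explicit closing vertex
        if len(verts) > 1 and np.allclose(verts[0], verts[-1]):
            verts = verts[:-1]
        if len(verts) < 3:
            raise RoiError(f"a polygon needs >= 3 vertices, got {len(verts)}")
        poly = Polygon(verts)
        if not poly.is_simple or not poly.is_valid:
            raise RoiError("polygon is self-intersecting or degenerate")
        object.__setattr__(self, "vertices", verts)

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass(frozen=True)
class NoduleMask:
    """Binary segmentation result with provenance.

    Invariants: the mask is a subset of the rasterized ROI, non-empty, and a
    single connected component (after largest-component selection and hole
    filling).
    """

    grid: np.ndarray
    threshold_used: float
    roi_ref: ROIPolygon | None = None
    connectivity: int = field(default=8)

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ValueError("mask grid must be 2D")
        if not grid.any():
            raise ValueError("mask is empty")
        object.__setattr__(self, "grid", grid)

    @property
    def pixel_count(self) -> int:
        return int(self.grid.sum())


def rasterize_roi(polygon: ROIPolygon, image_shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a polygon to a boolean grid by the pixel-center rule.

    A pixel belongs to the ROI iff its center lies inside the polygon
    (even-odd rule); a center exactly on the boundary is included.

    Parameters
    ----------
    polygon
        Simple polygon with vertices in ``(row, col)`` pixel coordinates.
    image_shape
        Shape of the target grid.

    Returns
    -------
    Boolean array of ``image_shape``; may be all-False if the polygon covers
    no pixel center (callers flag this downstream).
    """
    verts = polygon.vertices
    if (verts[:, 0].min() < -0.5 or verts[:, 1].min() < -0.5
            or verts[:, 0].max() > image_shape[0] - 0.5
            or verts[:, 1].max() > image_shape[1] - 0.5):
        raise RoiError("polygon extends outside the image bounds")
    poly = polygon.as_shapely()
    grid = np.zeros(image_shape, dtype=bool)
    # restrict the candidate window to the polygon bounding box
    r0 = max(int(np.floor(verts[:, 0].min())), 0)
    r1 = min(int(np.ceil(verts[:, 0].max())), image_shape[0] - 1)
    c0 = max(int(np.floor(verts[:, 1].min())), 0)
    c1 = min(int(np.ceil(verts[:, 1].max())), image_shape[1] - 1)
    if r1 < r0 or c1 < c0:
        return grid
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1),
                         indexing="ij")
    # shapely `covers` includes the boundary, i.e. ties resolve to inclusion
    flat = [poly.covers(Point(r, c)) for r, c in zip(rr.ravel(), cc.ravel())]
    grid[r0:r1 + 1, c0:c1 + 1] = np.asarray(flat).reshape(rr.shape)
    return grid


_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


def threshold_segment(image: HUImage, roi: np.ndarray,
                      threshold: float = DEFAULT_THRESHOLD_HU,
                      connectivity: int = 8,
                      fill_holes: bool = True) -> NoduleMask:
    """Segment a nodule inside an ROI by a fixed attenuation threshold.

    Pixels with attenuation >= ``threshold`` (inclusive) inside the ROI are
    kept; connected components are labelled (8-connectivity by default), the
    largest is retained, and interior holes (4-connected background regions
    not touching the outside) are filled.

    Raises
    ------
    SegmentationError
        If the ROI is empty or no pixel reaches the threshold; the error
        carries the HU range observed inside the ROI.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != image.shape:
        raise ValueError("ROI grid shape does not match the image")
    if not roi.any():
        raise SegmentationError("ROI covers no pixels")
    above = (image.values >= threshold) & roi
    if not above.any():
        vals = image.values[roi]
        raise SegmentationError(
            f"no nodule at threshold {threshold:g} HU: ROI attenuation range "
            f"[{vals.min():.1f}, {vals.max():.1f}] HU",
            hu_min=float(vals.min()), hu_max=float(vals.max()))
    struct = _STRUCT_8 if connectivity == 8 else _STRUCT_4
    labels, n = ndimage.label(above, structure=struct)
    if n > 1:
        sizes = ndimage.sum_labels(above, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        above = labels == keep
    if fill_holes:
        above = ndimage.binary_fill_holes(above, structure=_STRUCT_4)
        above &= roi  # hole filling cannot escape the ROI in practice; be strict
    return NoduleMask(grid=above, threshold_used=float(threshold),
                      connectivity=connectivity)


def select_largest_slice(stack: list[tuple[HUImage, ROIPolygon]],
                         threshold: float = DEFAULT_THRESHOLD_HU) -> int:
    """Index of the slice with the largest segmented cross-sectional area.

    Each slice is rasterized and segmented independently; areas are compared
    in mm^2 so anisotropic stacks are handled.  Ties go to the lowest index
    (logged).  Raises :class:`SegmentationError` if no slice is segmentable.
    """
    if not stack:
        raise ValueError("empty slice stack")
    areas: list[float] = []
    failures: list[str] = []
    for i, (img, roi_poly) in enumerate(stack):
        try:
            roi = rasterize_roi(roi_poly, img.shape)
            mask = threshold_segment(img, roi, threshold=threshold)
        except (SegmentationError, RoiError) as exc:
            areas.append(-1.0)
            failures.append(f"slice {i}: {exc}")
            continue
        areas.append(mask.pixel_count * img.pixel_area_mm2)
    if max(areas) < 0:
        raise SegmentationError(
            "no segmentable slice in stack: " + "; ".join(failures))
    best = int(np.argmax(areas))  # argmax takes the first maximum
    if areas.count(max(areas)) > 1:
        logger.info("largest-slice tie at %.3f mm^2, keeping lowest index %d",
                    max(areas), best)
    return best
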