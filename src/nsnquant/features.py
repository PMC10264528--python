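"""The 12 quantitative 2D CT features of a segmented nodule.

Features: (1) Feret's diameter (mean of the maximum and minimum Feret
diameters), (2) perimeter, (3) area, (4) mean, (5) median, (6) modal and
(7) standard deviation of CT attenuation, (8) linear mass density (LMD),
(9) skewness and (10) excess kurtosis of the attenuation histogram,
(11) circularity and (12) solidity.

Conventions (fixed for bit-reproducibility, documented in docs/methods.md):

* Perimeter is the length of the marching-squares 0.5-level contour between
  mask and background, so the circularity of a digital disk tends to 1.  A
  raw pixel-edge perimeter is available behind ``pixel_edge_perimeter``.
* Feret geometry is computed on the convex hull of the *pixel corners*, so
  a single pixel has a nonzero caliper diameter.
* Skewness/kurtosis use population (1/N) moments; the SD uses the sample
  (n-1) denominator.  Kurtosis is excess kurtosis (Gaussian -> 0).
* The mode is taken on integer-HU bins (values rounded to the nearest
  integer for the mode only); ties resolve to the lowest HU.
* LMD = area x (mean HU + 1000) / 1000, in mg/mm.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields
from typing import NamedTuple

import numpy as np
from scipy.spatial import ConvexHull
from skimage import measure

from .errors import DomainError
from .image import HUImage
from .segmentation import NoduleMask

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "feret_mean", "feret_max", "feret_min", "perimeter", "area",
    "mean_hu", "median_hu", "mode_hu", "sd_hu", "lmd",
    "skewness", "kurtosis", "circularity", "solidity",
)


@dataclass(frozen=True)
class FeatureVector:
    """Per-nodule quantitative CT features.

    ``flags`` records degenerate conditions (e.g. ``"sd_undefined"`` for a
    one-pixel region) instead of letting NaN propagate silently.
    """

    feret_mean: float   # mm
    feret_max: float    # mm
    feret_min: float    # mm
    perimeter: float    # mm
    area: float         # mm^2
    mean_hu: float      # HU
    median_hu: float    # HU
    mode_hu: float      # HU
    sd_hu: float        # HU
    lmd: float          # mg/mm
    skewness: float
    kurtosis: float     # excess
    circularity: float
    solidity: float
    flags: tuple[str, ...] = field(default=())

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError("area must be positive")
        expected = linear_mass_density(self.area, self.mean_hu)
        if not math.isclose(self.lmd, expected, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(
                f"inconsistent LMD {self.lmd!r}: area and mean attenuation "
                f"imply {expected!r}")


def measure_area(mask: NoduleMask | np.ndarray,
                 spacing: tuple[float, float]) -> float:
    """Mask area in mm^2: pixel count x row spacing x col spacing."""
    grid = mask.grid if isinstance(mask, NoduleMask) else np.asarray(mask, bool)
    n = int(grid.sum())
    if n == 0:
        raise ValueError("empty mask")
    return n * float(spacing[0]) * float(spacing[1])


def _smooth_closed_contour(contour: np.ndarray, window: int) -> np.ndarray:
    """Circular moving average of a closed polyline's vertices."""
    pts = contour[:-1]
    sm = np.zeros_like(pts)
    offsets = range(-(window // 2), window // 2 + 1)
    for off in offsets:
        sm += np.roll(pts, -off, axis=0)
    sm /= len(list(offsets))
    return np.vstack([sm, sm[:1]])


def trace_boundary(mask: NoduleMask | np.ndarray,
                   spacing: tuple[float, float] = (1.0, 1.0),
                   smooth_window: int | None = None) -> np.ndarray:
    """Outer closed contour of the mask at the 0.5 level, in mm.

    Marching squares between mask (1) and background (0); the mask is padded
    so objects touching the border still yield a closed loop.  When the mask
    has several contours (it should not, post-segmentation), the longest is
    returned.

    The raw marching-squares polyline of a binary mask is a staircase that
    overestimates the length of smooth boundaries by 5-7% regardless of
    size, so by default the vertices are regularized with a circular
    moving average (window 5), which brings the perimeter of digital disks
    and ellipses within 0.5% of the analytic value.  Contours with <= 12
    segments are left untouched, preserving the exact small-shape
    conventions (a single pixel is a diamond of length 2*sqrt(2)).  Pass
    ``smooth_window=1`` for the raw staircase.

    Returns an ``(n, 2)`` array of ``(row_mm, col_mm)`` vertices with
    ``vertices[0] == vertices[-1]``.
    """
    grid = mask.grid if isinstance(mask, NoduleMask) else np.asarray(mask, bool)
    padded = np.pad(grid.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("mask has no boundary (empty?)")
    contour = max(contours, key=len) - 1.0  # undo the pad offset
    if smooth_window is None:
        smooth_window = 5 if len(contour) - 1 > 12 else 1
    if smooth_window > 1:
        contour = _smooth_closed_contour(
            np.vstack([contour, contour[:1]])
            if not np.allclose(contour[0], contour[-1]) else contour,
            smooth_window)[:-1]
    contour = contour * np.asarray(spacing, dtype=float)
    if not np.allclose(contour[0], contour[-1]):
        contour = np.vstack([contour, contour[:1]])
    return contour


def measure_perimeter(contour: np.ndarray) -> float:
    """Euclidean polyline length of a closed contour (mm)."""
    contour = np.asarray(contour, dtype=float)
    if not np.allclose(contour[0], contour[-1]):
        raise ValueError("contour is not closed")
    return float(np.linalg.norm(np.diff(contour, axis=0), axis=1).sum())


def pixel_edge_perimeter(mask: NoduleMask | np.ndarray,
                         spacing: tuple[float, float]) -> float:
    """Alternative perimeter: total length of exposed pixel edges (mm)."""
    grid = mask.grid if isinstance(mask, NoduleMask) else np.asarray(mask, bool)
    g = np.pad(grid, 1)
    row_mm, col_mm = float(spacing[0]), float(spacing[1])
    # horizontal edges (length = col spacing) where vertical neighbours differ
    horiz = np.count_nonzero(g[1:, :] != g[:-1, :]) * col_mm
    vert = np.count_nonzero(g[:, 1:] != g[:, :-1]) * row_mm
    return horiz + vert


def _corner_points(grid: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Unique pixel-corner coordinates of the mask, in mm."""
    rr, cc = np.nonzero(grid)
    offsets = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    pts = (np.stack([rr, cc], axis=1)[:, None, :] + offsets[None, :, :])
    pts = pts.reshape(-1, 2)
    pts = np.unique(pts, axis=0)
    return pts * np.asarray(spacing, dtype=float)


class FeretDiameters(NamedTuple):
    max: float
    min: float
    mean: float


def feret_diameters(mask: NoduleMask | np.ndarray,
                    spacing: tuple[float, float]) -> FeretDiameters:
    """Maximum/minimum/mean Feret (caliper) diameters in mm.

    Computed on the convex hull of the mask's pixel corner points: the
    maximum Feret diameter is the largest distance between two hull
    vertices (antipodal pair), the minimum is the smallest width of the
    hull over all hull-edge normal directions (the minimal width of a
    convex polygon is always attained perpendicular to one of its edges).
    """
    grid = mask.grid if isinstance(mask, NoduleMask) else np.asarray(mask, bool)
    if not grid.any():
        raise ValueError("empty mask")
    pts = _corner_points(grid, spacing)
    hull = ConvexHull(pts)
    hp = pts[hull.vertices]
    # max caliper: brute force over hull vertex pairs (hulls are small)
    diff = hp[:, None, :] - hp[None, :, :]
    dmax = float(np.sqrt((diff ** 2).sum(-1)).max())
    # min width: for each hull edge, extent of projections onto its normal
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.linalg.norm(edges, axis=1)
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    proj = hp @ normals.T  # (n_points, n_edges)
    widths = proj.max(axis=0) - proj.min(axis=0)
    dmin = float(widths.min())
    return FeretDiameters(max=dmax, min=dmin, mean=(dmax + dmin) / 2.0)


class IntensityStats(NamedTuple):
    mean: float
    median: float
    mode: float
    sd: float
    flags: tuple[str, ...]


def intensity_stats(image: HUImage | np.ndarray,
                    mask: NoduleMask | np.ndarray) -> IntensityStats:
    """First-order attenuation statistics over the masked pixels.

    mean: arithmetic; median: midpoint-interpolated for even counts; mode:
    most frequent integer-HU bin, ties to the lowest HU; sd: sample
    standard deviation (n-1).  A single-pixel region flags the SD as
    undefined (NaN + ``"sd_undefined"``).
    """
    values = image.values if isinstance(image, HUImage) else np.asarray(image, float)
    grid = mask.grid if isinstance(mask, NoduleMask) else np.asarray(mask, bool)
    x = values[grid]
    if x.size == 0:
        raise ValueError("empty mask")
    flags: tuple[str, ...] = ()
    mean = float(x.mean())
    median = float(np.median(x))
    ints, counts = np.unique(np.rint(x).astype(np.int64), return_counts=True)
    mode = float(ints[counts == counts.max()].min())
    if x.size >= 2:
        sd = float(x.std(ddof=1))
    else:
        sd = float("nan")
        flags += ("sd_undefined",)
    return IntensityStats(mean, median, mode, sd, flags)


class HistogramMoments(NamedTuple):
    skewness: float
    kurtosis: float
    defined: bool


def histogram_moments(image: HUImage | np.ndarray,
                      mask: NoduleMask | np.ndarray) -> HistogramMoments:
    """Population-moment skewness and excess kurtosis of masked attenuations.

    skew = (1/N) sum(((x - mean)/sigma_N)^3); kurtosis = (1/N)
    sum(((x - mean)/sigma_N)^4) - 3, with sigma_N the population SD.  A
    zero-variance region returns NaNs with ``defined=False`` rather than
    propagating a division by zero.
    """
    values = image.values if isinstance(image, HUImage) else np.asarray(image, float)
    grid = mask.grid if isinstance(mask, NoduleMask) else np.asarray(mask, bool)
    x = values[grid].astype(float)
    if x.size < 3:
        raise ValueError("need >= 3 pixels for histogram moments")
    d = x - x.mean()
    m2 = float(np.mean(d ** 2))
    if m2 == 0.0:
        return HistogramMoments(float("nan"), float("nan"), False)
    skew = float(np.mean(d ** 3)) / m2 ** 1.5
    kurt = float(np.mean(d ** 4)) / m2 ** 2 - 3.0
    return HistogramMoments(skew, kurt, True)


def linear_mass_density(area_mm2: float, mean_hu: float) -> float:
    """Linear mass density in mg/mm: area x (mean HU + 1000) / 1000.

    The 2D analogue of nodule mass: attenuation re-expressed as a physical
    density (air -1000 HU -> 0 mg/mm^3, water 0 HU -> 1 mg/mm^3) times the
    cross-sectional area.
    """
    if mean_hu < -1000.0:
        raise DomainError(
            f"mean attenuation {mean_hu:g} HU is below -1000 (less than air)")
    return area_mm2 * (mean_hu + 1000.0) / 1000.0


class ShapeDescriptors(NamedTuple):
    circularity: float
    solidity: float


def shape_descriptors(area_mm2: float, perimeter_mm: float,
                      mask: NoduleMask | np.ndarray,
                      spacing: tuple[float, float]) -> ShapeDescriptors:
    """Circularity (4 pi A / P^2) and solidity (A / convex-hull area).

    Both are dimensionless in (0, 1].  Discretization can push raw
    circularity of near-circular digital shapes slightly above 1; such
    values are clamped to 1 with a log note.  Solidity uses the pixel-corner
    convex hull so a convex mask approaches 1 from below.
    """
    if perimeter_mm <= 0:
        raise ValueError("perimeter must be positive")
    circ = 4.0 * math.pi * area_mm2 / perimeter_mm ** 2
    if circ > 1.0:
        logger.info("raw circularity %.5f > 1 (quantization), clamped", circ)
        circ = 1.0
    grid = mask.grid if isinstance(mask, NoduleMask) else np.asarray(mask, bool)
    hull = ConvexHull(_corner_points(grid, spacing))
    solidity = min(area_mm2 / hull.volume, 1.0)  # 2D ConvexHull.volume is area
    return ShapeDescriptors(circ, solidity)


def extract_features(image: HUImage, mask: NoduleMask) -> FeatureVector:
    """Compute the full 12-feature vector for one segmented nodule."""
    spacing = image.pixel_spacing
    area = measure_area(mask, spacing)
    contour = trace_boundary(mask, spacing)
    perim = measure_perimeter(contour)
    feret = feret_diameters(mask, spacing)
    stats = intensity_stats(image, mask)
    flags = stats.flags
    if mask.pixel_count >= 3 and not math.isnan(stats.sd) and stats.sd > 0:
        moments = histogram_moments(image, mask)
        if not moments.defined:
            flags += ("moments_undefined",)
    else:
        moments = HistogramMoments(float("nan"), float("nan"), False)
        flags += ("moments_undefined",)
    shape = shape_descriptors(area, perim, mask, spacing)
    return FeatureVector(
        feret_mean=feret.mean, feret_max=feret.max, feret_min=feret.min,
        perimeter=perim, area=area,
        mean_hu=stats.mean, median_hu=stats.median, mode_hu=stats.mode,
        sd_hu=stats.sd, lmd=linear_mass_density(area, stats.mean),
        skewness=moments.skewness, kurtosis=moments.kurtosis,
        circularity=shape.circularity, solidity=shape.solidity,
        flags=flags)


def _unchecked_vector(**kwargs) -> FeatureVector:
    """Build a FeatureVector bypassing the LMD consistency check.

    Used for element-wise averaged vectors: the mean of two internally
    consistent LMDs need not equal area_avg x (mean_avg + 1000)/1000 when
    area and attenuation both vary between the repeats.
    """
    vec = object.__new__(FeatureVector)
    defaults = {"flags": ()}
    defaults.update(kwargs)
    for f in fields(FeatureVector):
        object.__setattr__(vec, f.name, defaults[f.name])
    return vec


def average_repeats(a: FeatureVector, b: FeatureVector) -> FeatureVector:
    """Element-wise mean of two repeated measurements of the same nodule.

    All 12 features (14 stored fields) are averaged independently; this is
    the repeat-measurement averaging applied before any downstream
    analysis, and it explains half-integer modal values in averaged tables.
    """
    merged = {name: (getattr(a, name) + getattr(b, name)) / 2.0
              for name in FEATURE_NAMES}
    return _unchecked_vector(
        **merged, flags=tuple(sorted(set(a.flags) | set(b.flags))))
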