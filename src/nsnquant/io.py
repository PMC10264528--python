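"""Reading and writing calibrated CT slices and ROI vertex files.

Two on-disk forms are supported:

* single-frame CT DICOM: attenuation = stored value * RescaleSlope +
  RescaleIntercept; PixelSpacing gives (row mm, col mm);
* a 16-bit TIFF/PNG raster with a JSON sidecar (same basename, ``.json``)
  holding ``{"rescale_slope", "rescale_intercept", "pixel_spacing"}``.

Images without spacing metadata are refused: every geometric feature is
reported in millimetres.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from PIL import Image as PILImage

from .image import HUImage
from .segmentation import ROIPolygon

_RASTER_SUFFIXES = {".tif", ".tiff", ".png"}


def read_ct(path: str | Path) -> HUImage:
    """Read a calibrated CT slice as an :class:`HUImage`."""
    path = Path(path)
    if path.suffix.lower() in _RASTER_SUFFIXES:
        return _read_raster(path)
    return _read_dicom(path)


def _read_dicom(path: Path) -> HUImage:
    ds = pydicom.dcmread(path)
    if "PixelSpacing" not in ds:
        raise ValueError(f"{path}: DICOM has no PixelSpacing; refusing "
                         "uncalibrated geometry")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    values = ds.pixel_array.astype(float) * slope + intercept
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    return HUImage(values=values, pixel_spacing=spacing)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _read_raster(path: Path) -> HUImage:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"{path}: missing JSON sidecar {sidecar.name} with "
                         "rescale and pixel-spacing metadata")
    meta = json.loads(sidecar.read_text())
    for key in ("rescale_slope", "rescale_intercept", "pixel_spacing"):
        if key not in meta:
            raise ValueError(f"{sidecar}: missing {key!r}")
    if path.suffix.lower() == ".png":
        stored = np.asarray(PILImage.open(path), dtype=float)
    else:
        stored = tifffile.imread(path).astype(float)
    values = stored * float(meta["rescale_slope"]) + float(meta["rescale_intercept"])
    spacing = tuple(float(s) for s in meta["pixel_spacing"])
    return HUImage(values=values, pixel_spacing=spacing)


def write_ct(image: HUImage, path: str | Path,
             rescale_intercept: float = -1024.0,
             rescale_slope: float = 1.0) -> Path:
    """Write an HU image as 16-bit TIFF + JSON sidecar (lossless for
    integer-valued HU grids under slope 1)."""
    path = Path(path)
    if path.suffix.lower() not in {".tif", ".tiff"}:
        raise ValueError("write_ct writes TIFF rasters; use a .tif path")
    stored = np.rint((image.values - rescale_intercept) / rescale_slope)
    if stored.min() < 0 or stored.max() > np.iinfo(np.uint16).max:
        raise ValueError("HU range does not fit the 16-bit stored scale")
    tifffile.imwrite(path, stored.astype(np.uint16))
    _sidecar_path(path).write_text(json.dumps({
        "rescale_slope": rescale_slope,
        "rescale_intercept": rescale_intercept,
        "pixel_spacing": list(image.pixel_spacing),
    }, indent=1))
    return path


def read_roi(path: str | Path) -> ROIPolygon:
    """Read a polygonal ROI from a two-column ``row col`` text file
    (comments with ``#``, comma or whitespace separated)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().replace(",", " ")
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}: expected 'row col' pairs, got {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    return ROIPolygon(vertices=np.asarray(rows))


def write_roi(polygon: ROIPolygon, path: str | Path) -> Path:
    path = Path(path)
    lines = ["# ROI vertices: row col (pixel coordinates)"]
    lines += [f"{r:.4f} {c:.4f}" for r, c in polygon.vertices]
    path.write_text("\n".join(lines) + "\n")
    return path
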