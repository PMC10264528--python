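"""Calibrated 2D attenuation grids.

Coordinate convention (used everywhere in the package): 0-based ``(row,
col)`` indices, pixel centers at integer coordinates, so the pixel ``(r,
c)`` occupies the square ``[r - 0.5, r + 0.5] x [c - 0.5, c + 0.5]`` in
pixel units.  Physical positions are obtained by multiplying row/col by the
corresponding spacing component (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ORIGIN_CONVENTION = "0-based (row, col); pixel centers at integer coordinates"


@dataclass(frozen=True)
class HUImage:
    """A 2D grid of CT attenuation values in Hounsfield units.

    Parameters
    ----------
    values
        2D float array of attenuation (HU).  Air is about -1000 HU, water 0.
    pixel_spacing
        ``(row_mm, col_mm)`` physical size of one pixel.
    origin
        Coordinate convention tag; informational.
    """

    values: np.ndarray
    pixel_spacing: tuple[float, float]
    origin: str = field(default=ORIGIN_CONVENTION)

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2D grid, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("attenuation grid contains non-finite values")
        spacing = (float(self.pixel_spacing[0]), float(self.pixel_spacing[1]))
        if spacing[0] <= 0 or spacing[1] <= 0:
            raise ValueError(f"pixel spacing must be positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "pixel_spacing", spacing)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_mm2(self) -> float:
        """Physical area of one pixel in mm^2."""
        return self.pixel_spacing[0] * self.pixel_spacing[1]
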