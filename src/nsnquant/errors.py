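"""Exception hierarchy for nsnquant.

All package errors derive from :class:`NsnQuantError` so callers can catch
one base class at pipeline level while tests assert on specific subclasses.
"""


class NsnQuantError(Exception):
    """Base class for all nsnquant errors."""


class ParameterizationError(NsnQuantError, ValueError):
    """A requested synthetic-texture moment triple cannot be realized.

    Raised e.g. when a gamma attenuation law is asked for skewness <= 0:
    the gamma family only produces strictly positive skewness.
    """


class GrowthRealizationError(NsnQuantError, ValueError):
    """A requested growth factor would leave the nonsolid attenuation range."""


class SegmentationError(NsnQuantError, ValueError):
    """Segmentation failed (no pixels at or above threshold inside the ROI)."""

    def __init__(self, message: str, hu_min: float | None = None,
                 hu_max: float | None = None):
        super().__init__(message)
        #: HU range observed inside the ROI, for the failure report.
        self.hu_min = hu_min
        self.hu_max = hu_max


class RoiError(NsnQuantError, ValueError):
    """Invalid region of interest (too few vertices, self-intersection, ...)."""


class DomainError(NsnQuantError, ValueError):
    """An input is outside the mathematical domain of an operation
    (e.g. mean attenuation below -1000 HU, non-positive scan interval)."""


class SeparationWarningError(NsnQuantError, RuntimeError):
    """Raised only when a separated logistic fit is used where a converged
    model is required; ordinary fits report separation via a flag instead."""
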