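"""Doubling time and growing/nongrowing classification.

Growth of a nonsolid nodule is quantified on its linear mass density (LMD)
between a baseline and a follow-up scan using the exponential (Schwartz)
growth model:

    DT = interval * ln 2 / ln(LMD_followup / LMD_baseline)

A nodule whose LMD does not increase is assigned an infinite doubling time
rather than a negative one.  Nodules with DT strictly below the cutoff
(default 1,556 days) are labelled growing; DT equal to the cutoff is
nongrowing.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass

from .errors import DomainError
from .features import FeatureVector

DT_CUTOFF_DAYS = 1556.0

GROWING = "growing"
NONGROWING = "nongrowing"


@dataclass(frozen=True)
class NoduleTimepoint:
    """One scan of one nodule: acquisition date plus measured features."""

    scan_date: _dt.date
    features: FeatureVector


@dataclass(frozen=True)
class GrowthResult:
    interval: float          # days
    lmd_ratio: float         # LMD_followup / LMD_baseline
    doubling_time: float     # days; math.inf for stable/shrinking
    label: str               # GROWING or NONGROWING
    cutoff_used: float       # days

    def __post_init__(self):
        expected = (math.isfinite(self.doubling_time)
                    and self.doubling_time < self.cutoff_used)
        if (self.label == GROWING) != expected:
            raise ValueError("label inconsistent with doubling time and cutoff")


def doubling_time_from_lmd(lmd_baseline: float, lmd_followup: float,
                           interval_days: float) -> float:
    """Doubling time in days under the exponential model on LMD.

    Returns ``math.inf`` when the LMD did not increase (no positive
    variation).  Raises :class:`DomainError` for non-positive intervals or
    LMD values, where the model is undefined.
    """
    if interval_days <= 0:
        raise DomainError(f"scan interval must be positive, got {interval_days!r}")
    if lmd_baseline <= 0 or lmd_followup <= 0:
        raise DomainError("LMD values must be positive for the growth model")
    if lmd_followup <= lmd_baseline:
        return math.inf
    return interval_days * math.log(2.0) / math.log(lmd_followup / lmd_baseline)


def classify_growth(dt_days: float, cutoff: float = DT_CUTOFF_DAYS) -> str:
    """Growing iff the doubling time is strictly below the cutoff.

    The boundary case DT == cutoff is nongrowing, matching the paired
    definitions DT < cutoff (growing) and DT >= cutoff (nongrowing).
    """
    if not (dt_days > 0):
        raise DomainError(f"doubling time must be positive, got {dt_days!r}")
    return GROWING if dt_days < cutoff else NONGROWING


def doubling_time(baseline: NoduleTimepoint, followup: NoduleTimepoint,
                  cutoff: float = DT_CUTOFF_DAYS) -> GrowthResult:
    """Full growth assessment between two timepoints of the same nodule."""
    interval = (followup.scan_date - baseline.scan_date).days
    if interval <= 0:
        raise DomainError(
            f"follow-up date {followup.scan_date} is not after baseline "
            f"{baseline.scan_date}")
    lmd1, lmd2 = baseline.features.lmd, followup.features.lmd
    dt = doubling_time_from_lmd(lmd1, lmd2, interval)
    return GrowthResult(
        interval=float(interval), lmd_ratio=lmd2 / lmd1, doubling_time=dt,
        label=classify_growth(dt, cutoff), cutoff_used=float(cutoff))
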