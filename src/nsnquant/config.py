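"""Run configuration with the published default cutoffs.

Defaults: segmentation threshold -800 HU; growing/nongrowing doubling-time
cutoff 1,556 days; risk cutoffs skewness 0.90 and LMD 19.16 mg/mm.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    threshold_hu: float = -800.0
    dt_cutoff_days: float = 1556.0
    skewness_cutoff: float = 0.90
    lmd_cutoff: float = 19.16         # mg/mm
    p_enter: float = 0.05             # univariate screening significance
    p_remove: float = 0.10            # backward-elimination removal threshold
    seed: int = 0
    output_dir: str = "nsnquant_out"

    def __post_init__(self):
        for name in ("threshold_hu", "dt_cutoff_days", "skewness_cutoff",
                     "lmd_cutoff"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
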