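"""Synthetic lung-window CT data with known ground truth.

Every downstream stage (segmentation, feature extraction, growth scoring,
cohort statistics) is testable without patient data through three levels of
generator:

* :func:`render_nodule` — one ground-glass nodule on aerated-parenchyma
  background, with analytically known geometry and an interior attenuation
  law solved to hit a requested (mean, SD, skewness) triple;
* :func:`render_followup` — a paired follow-up scan realizing a configured
  linear-mass-density (LMD) growth factor;
* :func:`simulate_cohort` — a cohort of growing/nongrowing nodules whose
  per-group feature medians converge to configured targets.

Background parenchyma is Gaussian, default -900 +/- 50 HU; nodule interiors
sit in (-800, -200) HU so the fixed -800 HU threshold separates them.  The
interior law is a shifted gamma (location-scale-shape) solved from the
moment triple, because the gamma family gives closed-form control of the
strictly positive skewness typical of ground-glass histograms; a symmetric
Gaussian fallback serves requested skewness 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from .errors import GrowthRealizationError, ParameterizationError
from .features import FeatureVector, linear_mass_density
from .growth import DT_CUTOFF_DAYS, GROWING, NONGROWING, doubling_time_from_lmd
from .image import HUImage
from .segmentation import NoduleMask, threshold_segment

DEFAULT_BACKGROUND_MEAN = -900.0  # HU, aerated parenchyma
DEFAULT_BACKGROUND_SD = 50.0      # HU
DEFAULT_PIXEL_SPACING = 0.7       # mm, typical thin-section chest CT
SOLID_LIMIT_HU = -200.0           # above this the lesion is no longer nonsolid

_N_THETA = 2048  # angular samples for the analytic boundary polygon


# --------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class NoduleSpec:
    """Parameters of one synthetic ground-glass nodule.

    ``equivalent_diameter`` is the diameter of the circle with the same
    area as the nodule (mm); the default admissible range 6-30 mm mirrors
    the size window in which persistent nonsolid nodules are analysed.
    ``attenuation_law``: "auto" picks gamma for positive skewness and the
    Gaussian fallback for zero skewness.
    """

    shape_type: Literal["ellipse", "fourier_blob"] = "ellipse"
    equivalent_diameter: float = 10.0        # mm
    aspect_ratio: float = 1.0                # >= 1
    boundary_irregularity: float = 0.0       # [0, 1]
    attenuation_mean: float = -600.0         # HU
    attenuation_sd: float = 130.0            # HU
    attenuation_skewness: float = 0.8
    rotation_deg: float = 0.0
    attenuation_law: Literal["auto", "gamma", "gaussian"] = "auto"
    seed: int = 0
    #: admissible equivalent-diameter range (mm).  The default is the 6-30
    #: mm *baseline* inclusion window; follow-up renderings of grown
    #: nodules widen the upper bound.
    size_range: tuple[float, float] = (6.0, 30.0)

    def __post_init__(self):
        if not (-800.0 < self.attenuation_mean < SOLID_LIMIT_HU):
            raise ValueError(
                f"attenuation_mean must lie in (-800, {SOLID_LIMIT_HU:g}) HU "
                f"to stay nonsolid yet segmentable, got {self.attenuation_mean}")
        lo, hi = self.size_range
        if not (lo <= self.equivalent_diameter <= hi):
            raise ValueError(
                f"equivalent_diameter outside the {lo:g}-{hi:g} mm range: "
                f"{self.equivalent_diameter}")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect_ratio must be >= 1")
        if not (0.0 <= self.boundary_irregularity <= 1.0):
            raise ValueError("boundary_irregularity must be in [0, 1]")
        if self.attenuation_sd < 0:
            raise ValueError("attenuation_sd must be >= 0")


@dataclass(frozen=True)
class GrowthScenario:
    """Ground-truth growth between baseline and follow-up.

    With sign "+" the LMD factor is 2**(interval / DT); "0" keeps the LMD
    (a fresh noise realization only); "-" shrinks by 2**(-interval / DT).
    """

    true_doubling_time: float          # days; math.inf for stable
    scan_interval: float               # days
    lmd_change_sign: Literal["+", "0", "-"] = "+"

    def __post_init__(self):
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be positive")
        if self.lmd_change_sign in ("+", "-"):
            if not (math.isfinite(self.true_doubling_time)
                    and self.true_doubling_time > 0):
                raise ValueError(
                    f"sign '{self.lmd_change_sign}' requires a finite positive "
                    "doubling time")

    @property
    def lmd_ratio(self) -> float:
        if self.lmd_change_sign == "0":
            return 1.0
        expo = self.scan_interval / self.true_doubling_time
        return 2.0 ** (expo if self.lmd_change_sign == "+" else -expo)


# --------------------------------------------------------------------------
# boundary geometry

def _radius_profile(spec: NoduleSpec, theta: np.ndarray) -> np.ndarray:
    """Polar boundary radius R(theta) in mm, area-normalized to pi r0^2."""
    r0 = spec.equivalent_diameter / 2.0
    rot = math.radians(spec.rotation_deg)
    th = theta - rot
    if spec.shape_type == "ellipse":
        a = r0 * math.sqrt(spec.aspect_ratio)
        b = r0 / math.sqrt(spec.aspect_ratio)
        base = (a * b) / np.sqrt((b * np.cos(th)) ** 2 + (a * np.sin(th)) ** 2)
    elif spec.shape_type == "fourier_blob":
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))
        f = np.ones_like(th)
        for k in range(2, 7):
            amp = 0.5 * spec.boundary_irregularity / math.sqrt(k)
            phase = rng.uniform(0, 2 * math.pi)
            f += amp * np.cos(k * th + phase)
        f = np.maximum(f, 0.15)
        if spec.aspect_ratio > 1.0:
            a = math.sqrt(spec.aspect_ratio)
            f *= 1.0 / np.sqrt((np.cos(th) / a) ** 2 + (np.sin(th) * a) ** 2)
        base = r0 * f
    else:  # pragma: no cover - guarded by the Literal type
        raise ValueError(f"unknown shape_type {spec.shape_type!r}")
    # normalize so the polygon area is exactly pi r0^2:
    # area of a polar region = 1/2 integral R^2 dtheta
    area = 0.5 * np.trapezoid(
        np.concatenate([base, base[:1]]) ** 2,
        dx=2 * math.pi / len(theta))
    return base * math.sqrt(math.pi * r0 ** 2 / area)


def _boundary_polygon(spec: NoduleSpec) -> Polygon:
    theta = np.linspace(0.0, 2.0 * math.pi, _N_THETA, endpoint=False)
    r = _radius_profile(spec, theta)
    pts = np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    poly = Polygon(pts)
    # the inscribed N-gon slightly underestimates the continuous area;
    # rescale so the polygon area equals the nominal pi r0^2 exactly
    target = math.pi * (spec.equivalent_diameter / 2.0) ** 2
    return Polygon(pts * math.sqrt(target / poly.area))


def _analytic_shape_truth(poly: Polygon) -> dict[str, float]:
    """Area, perimeter, Feret diameters and shape descriptors of the ideal
    (pre-rasterization) boundary."""
    area = poly.area
    perim = poly.length
    hull = poly.convex_hull
    hp = np.asarray(hull.exterior.coords)[:-1]
    diff = hp[:, None, :] - hp[None, :, :]
    fmax = float(np.sqrt((diff ** 2).sum(-1)).max())
    edges = np.roll(hp, -1, axis=0) - hp
    lengths = np.linalg.norm(edges, axis=1)
    normals = np.stack([-edges[:, 1], edges[:, 0]], axis=1) / lengths[:, None]
    proj = hp @ normals.T
    fmin = float((proj.max(axis=0) - proj.min(axis=0)).min())
    return {
        "area": area, "perimeter": perim,
        "feret_max": fmax, "feret_min": fmin,
        "feret_mean": (fmax + fmin) / 2.0,
        "circularity": min(4.0 * math.pi * area / perim ** 2, 1.0),
        "solidity": min(area / hull.area, 1.0),
    }


# --------------------------------------------------------------------------
# interior attenuation law

def solve_attenuation_law(mean: float, sd: float, skewness: float,
                          law: str = "auto") -> dict:
    """Solve a sampling law for a requested (mean, SD, skewness) triple.

    gamma: shape k = 4/skew^2, scale = sd*skew/2, location = mean - k*scale
    (skewness of a gamma is 2/sqrt(k), so the triple is hit exactly in
    expectation).  gaussian: mean/sd only, skewness must be 0.
    """
    if sd == 0.0:
        return {"kind": "constant", "value": mean}
    if law == "auto":
        law = "gamma" if skewness > 0 else "gaussian"
    if law == "gamma":
        if skewness <= 0:
            raise ParameterizationError(
                "gamma attenuation law requires skewness > 0 (gamma skewness "
                f"is 2/sqrt(k) > 0); got {skewness}. Select the gaussian "
                "fallback for symmetric interiors.")
        k = 4.0 / skewness ** 2
        scale = sd * skewness / 2.0
        return {"kind": "gamma", "shape": k, "scale": scale,
                "loc": mean - k * scale}
    if law == "gaussian":
        if skewness != 0.0:
            raise ParameterizationError(
                f"gaussian law cannot realize skewness {skewness}; use the "
                "gamma law for positive skewness")
        return {"kind": "gaussian", "mean": mean, "sd": sd}
    raise ValueError(f"unknown attenuation law {law!r}")


def _sample_law(law: dict, n: int, rng: np.random.Generator) -> np.ndarray:
    if law["kind"] == "constant":
        return np.full(n, law["value"])
    if law["kind"] == "gamma":
        return law["loc"] + rng.gamma(law["shape"], law["scale"], size=n)
    return rng.normal(law["mean"], law["sd"], size=n)


# --------------------------------------------------------------------------
# rendering

@dataclass(frozen=True)
class RenderedNodule:
    """A rendered scan plus its ground truth."""

    image: HUImage
    truth: FeatureVector
    true_mask: NoduleMask
    spec: NoduleSpec
    background_mean: float
    background_sd: float


def render_nodule(spec: NoduleSpec,
                  background_mean: float = DEFAULT_BACKGROUND_MEAN,
                  background_sd: float = DEFAULT_BACKGROUND_SD,
                  pixel_spacing: float | tuple[float, float] = DEFAULT_PIXEL_SPACING,
                  margin_mm: float = 5.0,
                  pv_blend: bool = True) -> RenderedNodule:
    """Render one nodule on parenchyma background.

    The ground-truth feature vector combines the analytically known
    boundary geometry (area, Feret diameters, perimeter, shape
    descriptors of the ideal polygon) with the attenuation moments of the
    rendered pixels under the true mask; its LMD ties the analytic area to
    the sampled pixel mean.  ``pv_blend`` adds a one-pixel linear
    partial-volume band at the boundary (off: hard edge).
    """
    if isinstance(pixel_spacing, (int, float)):
        spacing = (float(pixel_spacing), float(pixel_spacing))
    else:
        spacing = (float(pixel_spacing[0]), float(pixel_spacing[1]))
    if spacing[0] <= 0 or spacing[1] <= 0:
        raise ValueError("pixel_spacing must be positive")
    law = solve_attenuation_law(spec.attenuation_mean, spec.attenuation_sd,
                                spec.attenuation_skewness, spec.attenuation_law)

    theta = np.linspace(0.0, 2.0 * math.pi, _N_THETA, endpoint=False)
    radius = _radius_profile(spec, theta)
    r_max = float(radius.max())
    n_rows = int(math.ceil((2 * r_max + 2 * margin_mm) / spacing[0])) | 1
    n_cols = int(math.ceil((2 * r_max + 2 * margin_mm) / spacing[1])) | 1
    center = ((n_rows - 1) / 2.0 * spacing[0], (n_cols - 1) / 2.0 * spacing[1])

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    img = rng.normal(background_mean, background_sd, size=(n_rows, n_cols))

    yy = np.arange(n_rows)[:, None] * spacing[0] - center[0]
    xx = np.arange(n_cols)[None, :] * spacing[1] - center[1]
    rho = np.hypot(yy, xx)
    ang = np.arctan2(xx, yy) % (2.0 * math.pi)  # row axis as reference; arbitrary
    r_bound = np.interp(ang, theta, radius, period=2.0 * math.pi)
    sdist = rho - r_bound  # approximate signed distance (mm), <0 inside
    if pv_blend:
        h = 0.5 * (spacing[0] + spacing[1])
        cov = np.clip(0.5 - sdist / h, 0.0, 1.0)
    else:
        cov = (sdist <= 0.0).astype(float)

    touched = cov > 0.0
    nod_vals = _sample_law(law, int(touched.sum()), rng)
    blended = (1.0 - cov[touched]) * img[touched] + cov[touched] * nod_vals
    img[touched] = np.maximum(img[touched], blended)
    np.clip(img, -1024.0, 3071.0, out=img)  # scanner HU dynamic range

    mask_grid = sdist <= 0.0
    if not mask_grid.any():
        raise ValueError("nodule smaller than one pixel at this spacing")
    true_mask = NoduleMask(grid=mask_grid, threshold_used=float("nan"))

    shape_truth = _analytic_shape_truth(_boundary_polygon(spec))
    x = img[mask_grid]
    mean = float(x.mean())
    flags: tuple[str, ...] = ()
    sd = float(x.std(ddof=1)) if x.size >= 2 else float("nan")
    if x.size < 2:
        flags += ("sd_undefined",)
    d = x - x.mean()
    m2 = float(np.mean(d ** 2))
    if m2 > 0:
        skew = float(np.mean(d ** 3)) / m2 ** 1.5
        kurt = float(np.mean(d ** 4)) / m2 ** 2 - 3.0
    else:
        skew = kurt = float("nan")
        flags += ("moments_undefined",)
    ints, counts = np.unique(np.rint(x).astype(np.int64), return_counts=True)
    truth = FeatureVector(
        feret_mean=shape_truth["feret_mean"], feret_max=shape_truth["feret_max"],
        feret_min=shape_truth["feret_min"], perimeter=shape_truth["perimeter"],
        area=shape_truth["area"], mean_hu=mean, median_hu=float(np.median(x)),
        mode_hu=float(ints[counts == counts.max()].min()), sd_hu=sd,
        lmd=linear_mass_density(shape_truth["area"], mean),
        skewness=skew, kurtosis=kurt,
        circularity=shape_truth["circularity"],
        solidity=shape_truth["solidity"], flags=flags)
    return RenderedNodule(
        image=HUImage(values=img, pixel_spacing=spacing), truth=truth,
        true_mask=true_mask, spec=spec,
        background_mean=background_mean, background_sd=background_sd)


def render_followup(baseline: RenderedNodule, scenario: GrowthScenario,
                    area_density_split: float = 0.5,
                    pv_blend: bool = True,
                    adaptive_split: bool = False) -> tuple[RenderedNodule, float]:
    """Render the follow-up scan realizing a configured LMD growth factor.

    The LMD factor 2**(interval/DT) is split geometrically between the area
    (factor ``ratio**split``) and the mass-equivalent attenuation
    ``mean + 1000`` (factor ``ratio**(1-split)``), because LMD couples size
    and density and either channel alone is a degenerate test case.  A
    factor whose density share would push the mean attenuation out of the
    nonsolid window (-800, -200) HU is refused with a diagnostic; with
    ``adaptive_split=True`` the excess is shifted into the area channel
    instead (large, fast-growing lesions grow mostly in size).
    Returns the follow-up rendering and the exact ground-truth LMD ratio.
    """
    if not (0.0 <= area_density_split <= 1.0):
        raise ValueError("area_density_split must be in [0, 1]")
    ratio = scenario.lmd_ratio
    dens_factor = ratio ** (1.0 - area_density_split)
    spec = baseline.spec
    mass_hu = spec.attenuation_mean + 1000.0
    if adaptive_split:
        # keep the follow-up mean inside (-795, -210) HU, the rest to area
        dens_factor = float(np.clip(dens_factor, 205.0 / mass_hu,
                                    790.0 / mass_hu))
    area_factor = ratio / dens_factor
    new_mean = mass_hu * dens_factor - 1000.0
    if new_mean >= SOLID_LIMIT_HU:
        raise GrowthRealizationError(
            f"requested LMD factor {ratio:.3f} would raise mean attenuation to "
            f"{new_mean:.1f} HU (>= {SOLID_LIMIT_HU:g} HU): the lesion would "
            "no longer be nonsolid")
    if new_mean <= -800.0:
        raise GrowthRealizationError(
            f"requested LMD factor {ratio:.3f} would lower mean attenuation to "
            f"{new_mean:.1f} HU, below the -800 HU segmentation threshold")
    new_d = spec.equivalent_diameter * math.sqrt(area_factor)
    new_seed = int(np.random.SeedSequence([spec.seed, 2]).generate_state(1)[0]
                   % (2 ** 31))
    lo, hi = spec.size_range
    new_spec = replace(spec, equivalent_diameter=new_d,
                       attenuation_mean=new_mean, seed=new_seed,
                       size_range=(min(lo, new_d), max(hi, new_d)))
    followup = render_nodule(
        new_spec, background_mean=baseline.background_mean,
        background_sd=baseline.background_sd,
        pixel_spacing=baseline.image.pixel_spacing, pv_blend=pv_blend)
    return followup, ratio


# --------------------------------------------------------------------------
# cohort simulation

@dataclass(frozen=True)
class EffectSize:
    """Group-conditional location/scale for one feature.

    Positive-valued features are drawn log-normally (median + quartile
    spread), signed features normally (median + IQR/1.349 as SD).
    """

    median_growing: float
    median_nongrowing: float
    iqr_growing: float
    iqr_nongrowing: float

    @classmethod
    def coerce(cls, value) -> "EffectSize":
        if isinstance(value, cls):
            return value
        vals = tuple(float(v) for v in value)
        if len(vals) == 3:
            return cls(vals[0], vals[1], vals[2], vals[2])
        return cls(*vals)

    def __post_init__(self):
        if self.iqr_growing <= 0 or self.iqr_nongrowing <= 0:
            raise ValueError("IQR scales must be positive")


#: Default group-conditional targets, emulating the growing-vs-nongrowing
#: contrasts reported for persistent nonsolid nodule cohorts (median, IQR).
DEFAULT_EFFECT_SIZES: dict[str, EffectSize] = {
    "lmd": EffectSize(26.63, 12.81, 20.63, 7.92),
    "skewness": EffectSize(1.12, 0.65, 0.39, 0.38),
    "mean_hu": EffectSize(-609.27, -631.60, 82.46, 104.89),
    "sd_hu": EffectSize(148.04, 121.01, 46.09, 53.47),
    "kurtosis": EffectSize(1.19, -0.08, 1.30, 1.02),
    "circularity": EffectSize(0.56, 0.72, 0.12, 0.13),
    "solidity": EffectSize(0.71, 0.83, 0.15, 0.13),
}

#: Cohort covariate prevalences (proportions).
DEFAULT_COVARIATE_PREVALENCES: dict[str, float] = {
    "male": 0.417,
    "smoker": 0.400,
    "cancer_history": 0.483,
    "emphysema": 0.150,
    "upper_lobe": 0.750,
}



@dataclass(frozen=True)
class CohortConfig:
    """Configuration of a simulated growing/nongrowing nodule cohort."""

    n_nodules: int = 60
    growing_fraction: float = 19.0 / 60.0
    effect_sizes: dict[str, EffectSize] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    covariate_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_PREVALENCES))
    age_mean: float = 64.6              # years
    age_sd: float = 11.4
    dt_median: float = 2816.0           # days, nodules with positive LMD change
    dt_log_sigma: float = 1.502
    stable_fraction: float = 0.25       # nongrowing nodules with no LMD increase
    interval_median: float = 1136.0     # days between baseline and follow-up
    interval_log_sigma: float = 0.658
    dt_cutoff: float = DT_CUTOFF_DAYS
    render_images: bool = False
    pixel_spacing: float = DEFAULT_PIXEL_SPACING
    seed: int = 0

    def __post_init__(self):
        if self.n_nodules < 1:
            raise ValueError("n_nodules must be >= 1")
        if not (0.0 <= self.growing_fraction <= 1.0):
            raise ValueError("growing_fraction must be in [0, 1]")
        coerced = {k: EffectSize.coerce(v) for k, v in self.effect_sizes.items()}
        missing = {"lmd", "skewness"} - set(coerced)
        if missing:
            raise ValueError(f"effect_sizes must cover at least LMD and "
                             f"skewness; missing {sorted(missing)}")
        object.__setattr__(self, "effect_sizes", coerced)
        for name, p in self.covariate_prevalences.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")


@dataclass(frozen=True)
class CohortRecord:
    """One simulated nodule: scan pair (optional) plus ground truth."""

    nodule_id: int
    group: str
    true_doubling_time: float
    scan_interval: float
    covariates: dict[str, float]
    baseline: RenderedNodule | None = None
    followup: RenderedNodule | None = None
    true_lmd_ratio: float | None = None


def _draw_feature(effect: EffectSize, growing: bool, lognormal: bool,
                  rng: np.random.Generator) -> float:
    med = effect.median_growing if growing else effect.median_nongrowing
    iqr = effect.iqr_growing if growing else effect.iqr_nongrowing
    if lognormal:
        lo, hi = med - iqr / 2.0, med + iqr / 2.0
        if lo <= 0:  # fall back to a normal truncated at a small floor
            return max(rng.normal(med, iqr / 1.349), med * 0.05)
        s = math.log(hi / lo) / 1.349
        return float(med * math.exp(rng.normal(0.0, s)))
    return float(rng.normal(med, iqr / 1.349))


def _draw_doubling_time(growing: bool, cfg: CohortConfig,
                        rng: np.random.Generator) -> float:
    """Rejection-sample a DT on the group's side of the cutoff."""
    if not growing and rng.uniform() < cfg.stable_fraction:
        return math.inf
    mu = math.log(cfg.dt_median)
    for _ in range(10_000):
        dt = math.exp(rng.normal(mu, cfg.dt_log_sigma))
        if growing and dt < cfg.dt_cutoff:
            return dt
        if not growing and dt >= cfg.dt_cutoff:
            return dt
    raise RuntimeError("doubling-time rejection sampling failed")  # pragma: no cover


def _log_sigma(effect: EffectSize, growing: bool) -> float:
    med = effect.median_growing if growing else effect.median_nongrowing
    iqr = effect.iqr_growing if growing else effect.iqr_nongrowing
    lo, hi = med - iqr / 2.0, med + iqr / 2.0
    if lo <= 0:
        return 0.5
    return math.log(hi / lo) / 1.349


def _growth_score_variance(cfg: CohortConfig) -> float:
    """Within-group variance of the latent growth-likeness score."""
    skew = cfg.effect_sizes["skewness"]
    lmd = cfg.effect_sizes["lmd"]
    sep_skew = skew.median_growing - skew.median_nongrowing
    sep_lmd = math.log(lmd.median_growing / lmd.median_nongrowing)
    vz_skew = ((skew.iqr_growing + skew.iqr_nongrowing) / 2.0
               / 1.349 / sep_skew) ** 2
    s_log = (_log_sigma(lmd, True) + _log_sigma(lmd, False)) / 2.0
    vz_lmd = (s_log / sep_lmd) ** 2
    return (vz_skew + vz_lmd) / 4.0


def _sample_feature_row(growing: bool, cfg: CohortConfig,
                        rng: np.random.Generator) -> dict[str, float]:
    """Draw one nodule's 12-feature row.

    Skewness and LMD — the growth drivers — are drawn from the configured
    group-conditional laws.  Every other feature is generated from the
    nodule's latent growth-likeness score (a symmetric combination of the
    standardized skewness and log-LMD) plus independent noise, so that
    conditionally on skewness and LMD the remaining features carry no
    additional outcome information: the multivariable model should retain
    the two drivers and discard the rest, while per-group feature medians
    still converge to the configured targets.  Size features (area, Feret,
    perimeter) are derived from LMD, mean attenuation and circularity so
    each row is internally consistent.
    """
    eff = cfg.effect_sizes
    row: dict[str, float] = {}
    row["skewness"] = _draw_feature(eff["skewness"], growing, False, rng)
    row["lmd"] = max(_draw_feature(eff["lmd"], growing, True, rng), 0.5)

    skew_eff, lmd_eff = eff["skewness"], eff["lmd"]
    sep_skew = skew_eff.median_growing - skew_eff.median_nongrowing
    mid_skew = (skew_eff.median_growing + skew_eff.median_nongrowing) / 2.0
    sep_lmd = math.log(lmd_eff.median_growing / lmd_eff.median_nongrowing)
    mid_lmd = (math.log(lmd_eff.median_growing)
               + math.log(lmd_eff.median_nongrowing)) / 2.0
    z_skew = (row["skewness"] - mid_skew) / sep_skew
    z_lmd = (math.log(row["lmd"]) - mid_lmd) / sep_lmd
    score = (z_skew + z_lmd) / 2.0   # approx +/- 0.5 at the group medians
    var_s = _growth_score_variance(cfg)

    for name, effect in eff.items():
        if name in ("skewness", "lmd"):
            continue
        mid = (effect.median_growing + effect.median_nongrowing) / 2.0
        sep = effect.median_growing - effect.median_nongrowing
        target_sd = (effect.iqr_growing + effect.iqr_nongrowing) / 2.0 / 1.349
        noise_var = max(target_sd ** 2 - var_s * sep ** 2,
                        (0.3 * target_sd) ** 2)
        row[name] = mid + score * sep + rng.normal(0.0, math.sqrt(noise_var))
    row["mean_hu"] = float(np.clip(row.get("mean_hu", -600.0), -795.0, -210.0))
    row.setdefault("sd_hu", 130.0)
    row["sd_hu"] = max(row["sd_hu"], 5.0)
    row["circularity"] = float(np.clip(row.get("circularity", 0.7), 0.2, 1.0))
    row["solidity"] = float(np.clip(row.get("solidity", 0.8), 0.2, 1.0))
    row.setdefault("kurtosis", 0.3)
    row["area"] = 1000.0 * row["lmd"] / (row["mean_hu"] + 1000.0)
    eq_diam = 2.0 * math.sqrt(row["area"] / math.pi)
    shape_factor = 1.0 + 0.5 * (1.0 - row["circularity"]) + rng.normal(0, 0.03)
    row["feret_mean"] = eq_diam * max(shape_factor, 1.0)
    elong = abs(rng.normal(0.15, 0.05))
    row["feret_max"] = row["feret_mean"] * (1.0 + elong)
    row["feret_min"] = row["feret_mean"] * (1.0 - elong)
    row["perimeter"] = math.sqrt(4.0 * math.pi * row["area"]
                                 / row["circularity"])
    skew = row["skewness"]
    row["median_hu"] = row["mean_hu"] - row["sd_hu"] * skew / 6.0 \
        + rng.normal(0, 5.0)
    # Pearson mode approximation, snapped to the half-integer grid produced
    # by averaging two integer-binned modal values
    mode = 3.0 * row["median_hu"] - 2.0 * row["mean_hu"] + rng.normal(0, 15.0)
    row["mode_hu"] = round(mode * 2.0) / 2.0
    return row


def _draw_covariates(cfg: CohortConfig, rng: np.random.Generator) -> dict:
    cov = {name: int(rng.uniform() < p)
           for name, p in cfg.covariate_prevalences.items()}
    cov["age"] = float(rng.normal(cfg.age_mean, cfg.age_sd))
    return cov


def _spec_from_row(row: dict[str, float], seed: int) -> NoduleSpec:
    """Translate a sampled feature row into a renderable nodule spec."""
    eq_diam = float(np.clip(2.0 * math.sqrt(row["area"] / math.pi), 6.0, 30.0))
    irregularity = float(np.clip((0.95 - row["circularity"]) * 2.2, 0.0, 1.0))
    return NoduleSpec(
        shape_type="fourier_blob" if irregularity > 0.05 else "ellipse",
        equivalent_diameter=eq_diam,
        aspect_ratio=1.0 + float(np.clip(1.0 - row["solidity"], 0.0, 0.6)),
        boundary_irregularity=min(irregularity, 1.0),
        attenuation_mean=row["mean_hu"],
        attenuation_sd=row["sd_hu"],
        attenuation_skewness=max(row["skewness"], 0.05),
        seed=seed)


def simulate_cohort(config: CohortConfig) -> tuple[list[CohortRecord],
                                                   pd.DataFrame]:
    """Simulate a cohort of baseline/follow-up nodule pairs.

    Returns the per-nodule records and a truth table (one row per nodule)
    holding the 12 features, covariates, the assigned group and the true
    doubling time.  With ``render_images=True`` the features are *measured*
    by running threshold segmentation and feature extraction on rendered
    scans; otherwise they are drawn directly from the group-conditional
    laws.  Fully reproducible under ``config.seed``.
    """
    from .features import extract_features  # local import avoids cycle at module load

    rng = np.random.default_rng(config.seed)
    records: list[CohortRecord] = []
    rows: list[dict] = []
    for i in range(config.n_nodules):
        growing = bool(rng.uniform() < config.growing_fraction)
        true_dt = _draw_doubling_time(growing, config, rng)
        interval = float(np.exp(rng.normal(math.log(config.interval_median),
                                           config.interval_log_sigma)))
        if math.isfinite(true_dt):
            # fast growers are resected before many doublings accrue
            interval = min(interval, 4.0 * true_dt)
        covariates = _draw_covariates(config, rng)
        row = _sample_feature_row(growing, config, rng)
        baseline = followup = None
        ratio = None
        if config.render_images:
            seed_i = int(rng.integers(0, 2 ** 31 - 1))
            baseline = render_nodule(_spec_from_row(row, seed_i),
                                     pixel_spacing=config.pixel_spacing)
            scenario = GrowthScenario(
                true_doubling_time=true_dt, scan_interval=interval,
                lmd_change_sign="+" if math.isfinite(true_dt) else "0")
            followup, ratio = render_followup(baseline, scenario,
                                              adaptive_split=True)
            roi = ndimage.binary_dilation(baseline.true_mask.grid, iterations=3)
            seg = threshold_segment(baseline.image, roi)
            measured = extract_features(baseline.image, seg)
            row = {k: measured.as_dict()[k] for k in measured.as_dict()}
        group = GROWING if (math.isfinite(true_dt)
                            and true_dt < config.dt_cutoff) else NONGROWING
        records.append(CohortRecord(
            nodule_id=i, group=group, true_doubling_time=true_dt,
            scan_interval=interval, covariates=covariates,
            baseline=baseline, followup=followup, true_lmd_ratio=ratio))
        rows.append({"nodule_id": i, **row, **covariates,
                     "group": group, "growing": int(group == GROWING),
                     "doubling_time": true_dt, "scan_interval": interval})
    truth_table = pd.DataFrame(rows).set_index("nodule_id")
    return records, truth_table


def expected_skewness_auc(config: CohortConfig) -> float:
    """Analytic AUC of the skewness score under the configured effect size.

    Skewness is Gaussian within each group, so AUC = Phi(delta /
    sqrt(sg^2 + sn^2)) with delta the median separation and sg/sn the
    group SDs (IQR / 1.349).
    """
    eff = config.effect_sizes["skewness"]
    delta = eff.median_growing - eff.median_nongrowing
    sg = eff.iqr_growing / 1.349
    sn = eff.iqr_nongrowing / 1.349
    from scipy.stats import norm
    return float(norm.cdf(delta / math.hypot(sg, sn)))


def expected_skewness_cutoff(config: CohortConfig) -> float:
    """Population-optimal Youden cutoff of the skewness score.

    The Youden index is maximized where the two group densities cross;
    located numerically between the group medians.
    """
    from scipy.optimize import brentq
    from scipy.stats import norm
    eff = config.effect_sizes["skewness"]
    sg = eff.iqr_growing / 1.349
    sn = eff.iqr_nongrowing / 1.349

    def diff(x):
        return (norm.pdf(x, eff.median_growing, sg)
                - norm.pdf(x, eff.median_nongrowing, sn))

    return float(brentq(diff, eff.median_nongrowing, eff.median_growing))


def simulate_repeat_measurements(
        truth_table: pd.DataFrame, icc_target: float = 0.88,
        seed: int = 0,
        feature_names: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two rater-noise-perturbed copies of the feature columns.

    For each feature with between-nodule variance ``s2``, both copies add
    independent Gaussian noise with variance ``s2 * (1 - icc) / icc`` so the
    expected single-measurement absolute-agreement ICC equals
    ``icc_target``.
    """
    if not (0.0 < icc_target <= 1.0):
        raise ValueError("icc_target must be in (0, 1]")
    from .features import FEATURE_NAMES
    names = feature_names or tuple(n for n in FEATURE_NAMES
                                   if n in truth_table.columns)
    rng = np.random.default_rng(seed)
    set1 = truth_table[list(names)].copy()
    set2 = truth_table[list(names)].copy()
    for name in names:
        s2 = float(truth_table[name].var(ddof=1))
        noise_sd = math.sqrt(s2 * (1.0 - icc_target) / icc_target)
        set1[name] += rng.normal(0.0, noise_sd, len(set1))
        set2[name] += rng.normal(0.0, noise_sd, len(set2))
    return set1, set2
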