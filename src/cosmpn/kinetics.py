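"""First-order COS decay kinetics and biomass normalization.

Headspace COS in a sealed tube decays as ``C(t) = C0 * exp(-k t)``; ``k``
(h^-1 per tube) is obtained by ordinary least squares of ``ln C`` on ``t``
— closed-form, deterministic, and exact on noiseless exponential data.
Points censored at the GC detection limit are excluded from the fit.

Two derived statistics matter downstream:

* the rate constant normalized per gram dry sample (soils) or per mL
  (waters), comparable across environments; and
* SRCB, the Specific Rate Constant normalized by Biomass carbon:
  ``(k_suspension - k_blank) / biomass_mg_C`` (h^-1 mg^-1 C), comparable
  across isolates whose cultures reach very different cell yields.

Chemical hydrolysis of COS by water is the background every biological
signal sits on.  It is base-catalyzed, so it accelerates with pH; here it
is modelled as ``k_chem(pH) = k0 + kOH * [OH-]`` with ``[OH-] = 10^(pH-14)``
M, the minimal two-parameter form that passes exactly through two measured
(pH, 24-h fraction) anchor points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CalibrationError, InsufficientDataError
from .models import COSTimeCourse, SampleMetadata, hydroxide_molarity

#: biomass range (mg C) over which rate constants scale linearly with biomass
SRCB_LINEAR_RANGE_MG = (0.2, 5.0)


@dataclass(frozen=True)
class RateFit:
    """First-order decay fit for one tube: k (h^-1), fitted C0, r^2, n."""

    k_per_h: float
    c0_fit_ppmv: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class HydrolysisModel:
    """Base-catalyzed chemical hydrolysis: k(pH) = k0 + kOH*[OH-] (h^-1)."""

    k0_per_h: float
    k_oh_per_M_h: float

    def __post_init__(self) -> None:
        if self.k0_per_h < 0 or self.k_oh_per_M_h < 0:
            raise CalibrationError("hydrolysis rate terms must be non-negative")

    def k_per_h(self, pH: float) -> float:
        return self.k0_per_h + self.k_oh_per_M_h * hydroxide_molarity(pH)


@dataclass(frozen=True)
class BiomassCalibration:
    """Linear standard curve: instrument signal vs mg carbon (glucose)."""

    slope: float
    intercept: float
    standards_mg: tuple[float, ...] = (0.05, 0.5, 1.0, 3.0)

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError("biomass calibration slope must be positive")


@dataclass(frozen=True)
class SRCBValue:
    """Biomass-normalized specific rate constant (h^-1 mg^-1 C) with QC flag."""

    srcb: float
    k_suspension_per_h: float
    k_blank_per_h: float
    biomass_mg_c: float
    flag: str  # ok | negative | low_biomass


def fit_rate_constant(tc: COSTimeCourse) -> RateFit:
    """Fit C(t) = C0*exp(-k t) by log-linear least squares.

    Censored points (below the detection limit) are excluded.  Requires at
    least two usable points, all strictly positive.  With exactly two
    points (or zero residual) r^2 is 1 by convention.
    """
    t = np.asarray(tc.times_h, float)
    c = np.asarray(tc.concentrations_ppmv, float)
    usable = ~np.asarray(tc.below_detection, bool)
    t, c = t[usable], c[usable]
    if t.size < 2:
        raise InsufficientDataError(
            f"need >=2 uncensored points, have {t.size}"
        )
    if np.any(c <= 0):
        raise InsufficientDataError(
            "non-positive concentration among uncensored points; "
            "cannot take logarithms"
        )
    y = np.log(c)
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return RateFit(
        k_per_h=float(-slope),
        c0_fit_ppmv=float(math.exp(intercept)),
        r_squared=r2,
        n_points=int(t.size),
    )


def normalize_rate_constant(fit: RateFit, sample: SampleMetadata) -> float:
    """Per-tube k normalized to h^-1 (g dry)^-1 (soils) or h^-1 mL^-1 (waters)."""
    if sample.is_water:
        return fit.k_per_h / sample.volume_ml
    dry_g = sample.mass_used_g_wet * sample.dry_fraction
    if dry_g <= 0:
        raise InsufficientDataError("dry mass in assay tube must be positive")
    return fit.k_per_h / dry_g


def degradation_ratio(c0_ppmv: float, c_end_ppmv: float) -> float:
    """Percent of initial COS removed: 100*(1 - C_end/C0).

    May slightly exceed 100 (or dip below 0) under measurement noise; the
    raw value is returned, not clipped.
    """
    if c0_ppmv <= 0:
        raise InsufficientDataError("initial concentration must be positive")
    if c_end_ppmv < 0:
        raise InsufficientDataError("final concentration must be non-negative")
    return 100.0 * (1.0 - c_end_ppmv / c0_ppmv)


def calibrate_hydrolysis(
    anchors: Sequence[tuple[float, float]], duration_h: float = 24.0
) -> HydrolysisModel:
    """Solve k0, kOH so that 1-exp(-duration*k(pH)) matches two anchors exactly.

    ``anchors`` are two (pH, fraction-degraded-over-duration) pairs with
    distinct pH and fractions in (0, 1).  The 2x2 linear system in
    (k0, kOH) is solved analytically.
    """
    if len(anchors) != 2:
        raise CalibrationError("exactly two (pH, fraction) anchors required")
    (ph1, f1), (ph2, f2) = anchors
    if ph1 == ph2:
        raise CalibrationError("anchor pH values must be distinct")
    for f in (f1, f2):
        if not 0.0 < f < 1.0:
            raise CalibrationError(f"anchor fraction {f} outside (0, 1)")
    k1 = -math.log1p(-f1) / duration_h
    k2 = -math.log1p(-f2) / duration_h
    oh1, oh2 = hydroxide_molarity(ph1), hydroxide_molarity(ph2)
    k_oh = (k2 - k1) / (oh2 - oh1)
    k0 = k1 - k_oh * oh1
    if k_oh < 0 or k0 < 0:
        raise CalibrationError(
            f"anchors imply negative rate terms (k0={k0:.3e}, kOH={k_oh:.3e})"
        )
    return HydrolysisModel(k0_per_h=k0, k_oh_per_M_h=k_oh)


def chemical_fraction(model: HydrolysisModel, pH: float, duration_h: float) -> float:
    """Fraction of COS hydrolyzed chemically in ``duration_h`` hours at ``pH``."""
    if duration_h < 0:
        raise InsufficientDataError("duration must be non-negative")
    return 1.0 - math.exp(-duration_h * model.k_per_h(pH))


def fit_biomass_calibration(
    standards_mg: Sequence[float], signals: Sequence[float]
) -> BiomassCalibration:
    """Ordinary least squares of instrument signal on mg carbon standards."""
    x = np.asarray(standards_mg, float)
    y = np.asarray(signals, float)
    if x.size < 2 or x.size != y.size:
        raise CalibrationError("need >=2 matched standards and signals")
    slope, intercept = np.polyfit(x, y, 1)
    return BiomassCalibration(
        slope=float(slope), intercept=float(intercept), standards_mg=tuple(x)
    )


def biomass_carbon(signal: float, cal: BiomassCalibration) -> float:
    """Invert the standard curve: (signal - intercept)/slope, clamped at 0."""
    mg = (signal - cal.intercept) / cal.slope
    return max(0.0, mg)


def compute_srcb(
    k_suspension_per_h: float, k_blank_per_h: float, biomass_mg_c: float
) -> SRCBValue:
    """Specific rate constant normalized by biomass carbon.

    ``(k_suspension - k_blank)/biomass``; a negative difference is reported
    as-is with flag ``negative``; biomass outside the linear range
    (0.2–5 mg C) flags ``low_biomass``.
    """
    if biomass_mg_c <= 0:
        raise InsufficientDataError("biomass carbon must be positive")
    diff = k_suspension_per_h - k_blank_per_h
    srcb = diff / biomass_mg_c
    if diff < 0:
        flag = "negative"
    elif not SRCB_LINEAR_RANGE_MG[0] <= biomass_mg_c <= SRCB_LINEAR_RANGE_MG[1]:
        flag = "low_biomass"
    else:
        flag = "ok"
    return SRCBValue(
        srcb=srcb,
        k_suspension_per_h=k_suspension_per_h,
        k_blank_per_h=k_blank_per_h,
        biomass_mg_c=biomass_mg_c,
        flag=flag,
    )
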