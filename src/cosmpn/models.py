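"""Core domain types for two-step MPN experiments.

The experimental unit is a glass tube inoculated with 1 mL of a tenfold
serial dilution of an environmental suspension (soil: 3 g wet in 30 mL
total; water: the sample itself).  Each tube is scored for
chemoorganotrophic growth (turbidity) and, on several days, for carbonyl
sulfide (COS) degradation over a 24-h sealed incubation starting from a
nominal 30 ppmv headspace concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

SAMPLE_TYPES = ("forest_soil", "volcanic_ash", "scoria", "pond_water", "other")

#: GC flame-photometric detection limit for COS by direct injection (ppmv).
DETECTION_LIMIT_PPMV = 1.97


@dataclass(frozen=True)
class SampleMetadata:
    """Physico-chemical description of one environmental sample.

    ``water_content`` is a fraction of *wet* weight (0–1), ``toc`` a percent
    of dry weight for solids (percent for waters).  Exactly one of
    ``mass_used_g_wet`` (solid samples) or ``volume_ml`` (water samples)
    must be set; it is the amount placed in the rate-constant assay tube.
    """

    sample_id: str
    sample_type: str = "forest_soil"
    water_content: float = 0.0
    pH: float = 7.0
    toc: Optional[float] = None
    mass_used_g_wet: Optional[float] = None
    volume_ml: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(f"unknown sample_type {self.sample_type!r}")
        if not 0.0 <= self.water_content < 1.0:
            raise ValidationError(
                f"water_content must be in [0, 1), got {self.water_content}"
            )
        if not 0.0 < self.pH < 14.0:
            raise ValidationError(f"pH must be in (0, 14), got {self.pH}")
        if (self.mass_used_g_wet is None) == (self.volume_ml is None):
            raise ValidationError(
                "exactly one of mass_used_g_wet / volume_ml must be set"
            )
        if self.mass_used_g_wet is not None and self.mass_used_g_wet <= 0:
            raise ValidationError("mass_used_g_wet must be positive")
        if self.volume_ml is not None and self.volume_ml <= 0:
            raise ValidationError("volume_ml must be positive")

    @property
    def is_water(self) -> bool:
        return self.volume_ml is not None

    @property
    def dry_fraction(self) -> float:
        return 1.0 - self.water_content


@dataclass(frozen=True)
class DilutionDesign:
    """Geometry of the tenfold serial-dilution series.

    The primary suspension is ``soil_mass_g_wet`` grams of sample in
    ``soil_mass_g_wet + diluent_ml`` millilitres total (1 g taken as 1 mL).
    ``level_exponents`` are the decades of dilution of that suspension;
    a tube at level *e* receives ``inoculum_ml`` of the 10^-e dilution, i.e.
    ``soil_mass/(soil_mass+diluent) * inoculum_ml * base^-e`` grams wet.
    For water samples the dilution series starts from the sample itself and
    a level-*e* tube receives ``inoculum_ml * base^-e`` mL of sample.
    """

    soil_mass_g_wet: float = 3.0
    diluent_ml: float = 27.0
    inoculum_ml: float = 1.0
    tubes_per_level: int = 3
    level_exponents: tuple[int, ...] = tuple(range(2, 11))
    dilution_base: int = 10

    def __post_init__(self) -> None:
        exps = tuple(self.level_exponents)
        object.__setattr__(self, "level_exponents", exps)
        if any(b >= a for a, b in zip(exps[1:], exps)):
            raise ValidationError("level_exponents must be strictly increasing")
        if self.tubes_per_level < 1:
            raise ValidationError("tubes_per_level must be >= 1")
        if self.soil_mass_g_wet <= 0 or self.diluent_ml < 0 or self.inoculum_ml <= 0:
            raise ValidationError("suspension amounts must be positive")
        if self.dilution_base < 2:
            raise ValidationError("dilution_base must be >= 2")

    @property
    def suspension_volume_ml(self) -> float:
        return self.soil_mass_g_wet + self.diluent_ml

    def grams_wet_per_tube(self, level_exponent: int) -> float:
        """Grams of wet sample delivered to one tube at this level."""
        per_ml = self.soil_mass_g_wet / self.suspension_volume_ml
        return per_ml * self.inoculum_ml * self.dilution_base ** (-level_exponent)

    def ml_sample_per_tube(self, level_exponent: int) -> float:
        """Millilitres of original water sample delivered to one tube."""
        return self.inoculum_ml * self.dilution_base ** (-level_exponent)

    def inoculum_dry_g(self, level_exponent: int, sample: SampleMetadata) -> float:
        """Grams dry sample (or mL for waters) per tube at this level."""
        if sample.is_water:
            return self.ml_sample_per_tube(level_exponent)
        return self.grams_wet_per_tube(level_exponent) * sample.dry_fraction

    def relative_volumes(self, level_exponents: Sequence[int]) -> np.ndarray:
        """Inoculum volumes relative to the lowest exponent in the set."""
        exps = np.asarray(level_exponents)
        return np.asarray(self.dilution_base, float) ** -(exps - exps.min())


@dataclass
class TubeObservation:
    """One tube on one measurement day.

    At least one of ``turbid``, ``degradation_ratio_pct`` or
    ``residual_ppmv`` must be present; ``None`` marks a missing measurement
    (the table em-dash) and is distinct from zero.  Ratios slightly above
    100 % are retained (``overshoot`` set) rather than clipped.
    """

    level_exponent: int
    replicate: int
    day: float
    turbid: Optional[bool] = None
    degradation_ratio_pct: Optional[float] = None
    residual_ppmv: Optional[float] = None
    initial_ppmv: Optional[float] = None
    overshoot: bool = field(default=False, compare=False)

    #: relative tolerance allowed for residual > initial under GC noise
    RESIDUAL_TOLERANCE = 0.2

    def __post_init__(self) -> None:
        if (
            self.turbid is None
            and self.degradation_ratio_pct is None
            and self.residual_ppmv is None
        ):
            raise ValidationError(
                f"tube {self.level_exponent}-{self.replicate} day {self.day}: "
                "no measurement present"
            )
        if self.residual_ppmv is not None:
            if self.initial_ppmv is None:
                raise ValidationError("residual_ppmv given without initial_ppmv")
            if self.residual_ppmv > self.initial_ppmv * (1 + self.RESIDUAL_TOLERANCE):
                raise ValidationError(
                    f"residual {self.residual_ppmv} ppmv exceeds initial "
                    f"{self.initial_ppmv} ppmv beyond tolerance"
                )
        r = self.ratio_pct
        if r is not None and r > 100.0:
            self.overshoot = True

    @property
    def ratio_pct(self) -> Optional[float]:
        """Degradation ratio (%) — stored value, else derived from residual."""
        if self.degradation_ratio_pct is not None:
            return self.degradation_ratio_pct
        if self.residual_ppmv is not None and self.initial_ppmv:
            return 100.0 * (1.0 - self.residual_ppmv / self.initial_ppmv)
        return None


@dataclass(frozen=True)
class COSTimeCourse:
    """Headspace COS concentrations over time for one assay tube."""

    times_h: tuple[float, ...]
    concentrations_ppmv: tuple[float, ...]
    below_detection: tuple[bool, ...] = ()
    series_id: str = ""
    detection_limit_ppmv: float = DETECTION_LIMIT_PPMV

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times_h)
        c = tuple(float(x) for x in self.concentrations_ppmv)
        bd = tuple(bool(x) for x in self.below_detection) or (False,) * len(t)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "concentrations_ppmv", c)
        object.__setattr__(self, "below_detection", bd)
        if len(c) != len(t) or len(bd) != len(t):
            raise ValidationError("time/concentration/censoring lengths differ")
        if any(x < 0 for x in t) or any(nxt <= prev for prev, nxt in zip(t, t[1:])):
            raise ValidationError("times_h must be non-negative, strictly increasing")
        if any(x < 0 for x in c):
            raise ValidationError("concentrations must be non-negative")
        for conc, flag in zip(c, bd):
            if flag and conc > self.detection_limit_ppmv:
                raise ValidationError(
                    f"point flagged below detection but {conc} ppmv exceeds "
                    f"the {self.detection_limit_ppmv} ppmv limit"
                )

    def __len__(self) -> int:
        return len(self.times_h)


@dataclass(frozen=True)
class RunConfig:
    """Assay-level constants of the two-step MPN procedure."""

    positivity_threshold_pct: float = 40.0
    cos_initial_ppmv: float = 30.0
    assay_duration_h: float = 24.0
    detection_limit_ppmv: float = DETECTION_LIMIT_PPMV
    measurement_days: tuple[float, ...] = (4.0, 11.0, 18.0, 40.0)
    design: DilutionDesign = field(default_factory=DilutionDesign)
    hydrolysis_anchors: tuple[tuple[float, float], ...] = ((7.0, 0.26), (7.5, 0.32))

    def __post_init__(self) -> None:
        if not 0.0 < self.positivity_threshold_pct <= 100.0:
            raise ValidationError("positivity threshold must be in (0, 100]")
        if self.assay_duration_h <= 0:
            raise ValidationError("assay_duration_h must be positive")
        if self.cos_initial_ppmv <= 0:
            raise ValidationError("cos_initial_ppmv must be positive")
        object.__setattr__(
            self, "measurement_days", tuple(float(d) for d in self.measurement_days)
        )
        object.__setattr__(
            self,
            "hydrolysis_anchors",
            tuple((float(p), float(f)) for p, f in self.hydrolysis_anchors),
        )


def hydroxide_molarity(pH: float) -> float:
    """[OH-] in mol/L from pH at 25 °C (pKw = 14)."""
    return math.pow(10.0, pH - 14.0)
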