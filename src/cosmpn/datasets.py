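"""Packaged example data: the canonical forest-soil MPN experiment.

``karasawa_observations()`` is the published two-step MPN experiment on the
Mt. Karasawa forest soil (sample KS-13, 1/10-NBY medium): 9 dilution levels
(decades 2–10) x 3 replicates, with the COS degradation ratio (%) measured
on days 4, 11, 18 and 40 after inoculation.  One measurement (tube 7-2,
day 40) is missing.  Applying the inclusive >=40 % rule gives the
positive-tube pattern (3,3,3,3,3,3,1,1,0) across levels, i.e. "3, 1, 1"
at the three scoring levels 10^7–10^9, and a COS-degrader density of about
1e9 MPN per gram dry soil.

``environmental_samples()`` is the accompanying panel of 20 environmental
samples (forest soils, volcanic ash, scoria, pond waters) with water
content, pH, total organic carbon and the measured per-gram COS
degradation rate constant.
"""

from __future__ import annotations

import pandas as pd

from .models import DilutionDesign, SampleMetadata, TubeObservation

#: (level, replicate) -> degradation ratio % on days 4, 11, 18, 40 (None = missing)
_KARASAWA_RATIOS: dict[tuple[int, int], tuple] = {
    (2, 1): (97, 95, 85, 85),
    (2, 2): (100, 100, 100, 100),
    (2, 3): (100, 100, 100, 100),
    (3, 1): (100, 100, 100, 82),
    (3, 2): (100, 100, 100, 83),
    (3, 3): (100, 100, 100, 89),
    (4, 1): (74, 62, 55, 49),
    (4, 2): (96, 73, 72, 62),
    (4, 3): (44, 44, 41, 34),
    (5, 1): (41, 91, 92, 88),
    (5, 2): (42, 57, 42, 37),
    (5, 3): (38, 82, 90, 91),
    (6, 1): (22, 40, 41, 37),
    (6, 2): (23, 43, 41, 31),
    (6, 3): (28, 42, 46, 39),
    (7, 1): (58, 100, 69, 52),
    (7, 2): (25, 72, 74, None),
    (7, 3): (22, 29, 24, 65),
    (8, 1): (24, 29, 27, 29),
    (8, 2): (23, 28, 57, 39),
    (8, 3): (23, 26, 26, 26),
    (9, 1): (25, 28, 26, 28),
    (9, 2): (25, 27, 26, 26),
    (9, 3): (24, 27, 26, 46),
    (10, 1): (25, 27, 30, 27),
    (10, 2): (25, 26, 26, 27),
    (10, 3): (26, 26, 26, 27),
}

#: tubes scored turbid (chemoorganotrophic growth); the growth pattern at
#: the scoring levels 10^7-10^9 is (3, 1, 1), matching the COS pattern.
_KARASAWA_TURBID = frozenset(
    [(e, r) for e in range(2, 7) for r in (1, 2, 3)]
    + [(7, 1), (7, 2), (7, 3), (8, 2), (9, 3)]
)

_MEASUREMENT_DAYS = (4.0, 11.0, 18.0, 40.0)

KARASAWA_SAMPLE_ID = "KS-13"


def karasawa_design() -> DilutionDesign:
    """The published design: 3 g in 27 mL, 1 mL inocula, triplicates, 10^2-10^10."""
    return DilutionDesign(level_exponents=tuple(range(2, 11)))


def karasawa_sample() -> SampleMetadata:
    """Mt. Karasawa forest soil KS-13 (water content 29.7 %, pH 5.28)."""
    return SampleMetadata(
        sample_id=KARASAWA_SAMPLE_ID,
        sample_type="forest_soil",
        water_content=0.297,
        pH=5.28,
        toc=4.8,
        mass_used_g_wet=4.0,
    )


def karasawa_observations() -> list[TubeObservation]:
    """All 108 tube x day records of the KS-13 experiment (one missing ratio)."""
    obs = []
    for (level, rep), ratios in _KARASAWA_RATIOS.items():
        turbid = (level, rep) in _KARASAWA_TURBID
        for day, ratio in zip(_MEASUREMENT_DAYS, ratios):
            obs.append(
                TubeObservation(
                    level_exponent=level,
                    replicate=rep,
                    day=day,
                    turbid=turbid,
                    degradation_ratio_pct=None if ratio is None else float(ratio),
                )
            )
    return obs


#: sample_id, sample_type, water content (% wet), pH, TOC (%), rate constant
#: (h^-1 (g dry)^-1 for solids, h^-1 mL^-1 for waters)
_SAMPLES = [
    ("KS-13", "forest_soil", 29.7, 5.28, 4.8, 1.10),
    ("SG-1", "forest_soil", 31.0, 5.0, 5.2, 1.25),
    ("CL", "forest_soil", 46.1, 5.4, 7.0, 1.25),
    ("IG-C", "volcanic_ash", 25.3, 4.1, 0.05, 0.07),
    ("IG-2A", "forest_soil", 46.1, 4.4, 6.5, 1.18),
    ("OY-1-C", "volcanic_ash", 28.5, 3.6, 0.05, 0.01),
    ("OY-1-A", "forest_soil", 33.6, 4.2, 6.3, 0.66),
    ("KP-1", "scoria", 10.2, 4.9, 0.05, 0.05),
    ("KP-3", "scoria", 17.8, 4.9, 0.38, 0.22),
    ("KP-5", "scoria", 13.9, 4.6, 0.64, 0.36),
    ("F-1140", "forest_soil", 55.6, 4.8, 11.7, 1.71),
    ("F-1300", "forest_soil", 46.8, 5.4, 9.1, 1.40),
    ("F-1480", "scoria", 10.5, 5.4, 0.29, 0.60),
    ("F-3020", "scoria", 6.0, 5.9, 0.05, 0.27),
    ("F-3230", "scoria", 9.8, 6.1, 0.05, 0.27),
    ("F-3590", "scoria", 10.1, 5.5, 0.05, 0.35),
    ("F-3750", "scoria", 16.6, 5.6, 0.05, 0.26),
    ("Pond A", "pond_water", None, 7.6, 19.7, 0.051),
    ("Pond B", "pond_water", None, 7.7, 11.3, 0.035),
    ("Pond C", "pond_water", None, 7.4, 0.4, 0.019),
]


def environmental_samples() -> pd.DataFrame:
    """Metadata/rate panel for the 20 environmental samples (samples.csv shape).

    TOC values reported as "<0.1 %" are carried as 0.05.
    """
    return pd.DataFrame(
        _SAMPLES,
        columns=[
            "sample_id",
            "sample_type",
            "water_content_pct_wet",
            "pH",
            "toc_pct",
            "rate_constant",
        ],
    )
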