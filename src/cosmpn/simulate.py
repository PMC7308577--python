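"""Synthetic two-step MPN experiments with known ground truth.

The generator reproduces the statistical structure the estimators assume:

* **Poisson inoculation.**  A tube at dilution level *e* receives
  ``Poisson(density * grams-dry-equivalent)`` chemoorganotroph cells, of
  which a binomial share (``density_cos/density_het``) are COS degraders —
  so degraders are always a subset of growers.
* **Growth trajectory.**  Founded populations climb log-linearly (about
  ``log10(capacity)/growth_rise_d`` decades per day after a lag) to a
  biomass plateau of ``biomass_peak_mg`` mg C, then decline slowly; dilute
  tubes start from fewer cells and so turn COS-positive on later
  measurement days — the transient-positive phenomenon that motivates
  repeated scoring.
* **COS assay.**  The observed 24-h degradation fraction of a tube is
  ``1 - exp(-24*(k_chem(pH) + SRCB_tube * B_deg(day)))`` where ``B_deg`` is
  the degrader share of biomass and ``SRCB_tube`` is the mean specific
  activity of the tube's founding degrader lineages (lognormal per
  lineage; single-founder tubes at the extinction dilutions are the most
  variable, which is where transient calls arise); the chemical baseline
  comes from a calibrated hydrolysis model.  GC noise is multiplicative Gaussian on the residual
  concentration; residuals below the detection limit are flagged censored.

Everything is reproducible from ``SimConfig.seed`` alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinetics import HydrolysisModel, calibrate_hydrolysis
from .models import (
    DilutionDesign,
    RunConfig,
    SampleMetadata,
    TubeObservation,
)

#: cells per tube at the biomass plateau (sets how long dilute tubes lag)
CARRYING_CAPACITY_CELLS = 1e9

_DEFAULT_SAMPLE = SampleMetadata(
    sample_id="synthetic-forest-soil",
    sample_type="forest_soil",
    water_content=0.297,
    pH=5.28,
    toc=4.8,
    mass_used_g_wet=4.0,
)


def default_hydrolysis() -> HydrolysisModel:
    """Hydrolysis model calibrated to the 26%/32% anchors at pH 7.0/7.5."""
    return calibrate_hydrolysis([(7.0, 0.26), (7.5, 0.32)])


@dataclass(frozen=True)
class SimConfig:
    """Complete parameterization of one synthetic two-step MPN experiment.

    Densities are organisms per gram dry sample (per mL for waters).
    Per-lineage specific COS-degrading activity is lognormal —
    ``log10(activity) ~ Normal(log10(srcb_median), srcb_log10_sd)`` — with
    defaults matching the log-moments of measured isolate panels (median
    0.7 h^-1 mg^-1 C, spanning roughly 0.03–3); a tube's activity is the
    mean over its founding degrader lineages.  Trajectory
    parameters are in days (``growth_rise_d`` is the rise time of a
    single-cell inoculum; fuller tubes rise proportionally faster); GC
    noise is a multiplicative Gaussian sd in percent of the residual.
    """

    seed: int = 0
    density_het_per_g_dry: float = 9.6e8
    density_cos_per_g_dry: float = 9.6e8
    design: DilutionDesign = field(default_factory=DilutionDesign)
    sample: SampleMetadata = _DEFAULT_SAMPLE
    srcb_median_per_h_mg: float = 0.7
    srcb_log10_sd: float = 0.6
    biomass_peak_mg: float = 0.5
    growth_lag_d: float = 1.0
    growth_rise_d: float = 6.0
    decline_rate_per_d: float = 0.03
    hydrolysis: HydrolysisModel = field(default_factory=default_hydrolysis)
    medium_pH: float = 7.0
    cos_initial_ppmv: float = 30.0
    assay_duration_h: float = 24.0
    measurement_sd_pct: float = 5.0
    detection_limit_ppmv: float = 1.97
    measurement_days: tuple[float, ...] = (4.0, 11.0, 18.0, 40.0)

    def __post_init__(self) -> None:
        if self.density_cos_per_g_dry > self.density_het_per_g_dry:
            raise ValidationError("density_cos must not exceed density_het")
        for name in (
            "density_het_per_g_dry",
            "density_cos_per_g_dry",
            "srcb_log10_sd",
            "biomass_peak_mg",
            "growth_lag_d",
            "growth_rise_d",
            "decline_rate_per_d",
            "measurement_sd_pct",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")

    def run_config(self) -> RunConfig:
        return RunConfig(
            cos_initial_ppmv=self.cos_initial_ppmv,
            assay_duration_h=self.assay_duration_h,
            detection_limit_ppmv=self.detection_limit_ppmv,
            measurement_days=self.measurement_days,
            design=self.design,
        )


@dataclass(frozen=True)
class TubeTruth:
    """Ground truth for one simulated tube."""

    level_exponent: int
    replicate: int
    n_het_cells: int
    n_cos_cells: int
    srcb_per_h_mg: float
    biomass_trajectory: tuple[float, ...]  # mg C on each measurement day
    true_k_bio_by_day: tuple[float, ...]  # h^-1, biological component


def _biomass_mg(cfg: SimConfig, n_het: int, day: float) -> float:
    """Lag-rise-decline trajectory (piecewise linear in log10 biomass)."""
    if n_het < 1:
        return 0.0
    decades_total = math.log10(CARRYING_CAPACITY_CELLS)
    decades_to_climb = max(0.0, decades_total - math.log10(n_het))
    ramp = decades_total / cfg.growth_rise_d  # decades per day
    t_peak = cfg.growth_lag_d + decades_to_climb / ramp
    if day >= t_peak:
        drop = cfg.decline_rate_per_d * (day - t_peak)
    else:
        drop = ramp * (t_peak - day)
    return cfg.biomass_peak_mg * 10.0 ** (-drop)


def _tube_srcb(cfg: SimConfig, n_cos: int, rng: np.random.Generator) -> float:
    """Specific activity of one tube's degrader community (h^-1 mg^-1 C).

    Per-lineage activities are lognormal; under neutral competition each
    founding lineage reaches an equal biomass share, so the tube activity
    is the arithmetic mean over founders.  Exact for up to 100 founders;
    fuller tubes use the normal approximation of the mean (their activity
    is tightly concentrated anyway).
    """
    mu_ln = math.log(cfg.srcb_median_per_h_mg)
    sd_ln = cfg.srcb_log10_sd * math.log(10.0)
    k = max(n_cos, 1)  # n_cos=0 still consumes one draw (stream stability)
    if k <= 100:
        return float(np.mean(rng.lognormal(mu_ln, sd_ln, size=k)))
    mean_lin = math.exp(mu_ln + 0.5 * sd_ln**2)
    sd_lin = mean_lin * math.sqrt(math.expm1(sd_ln**2))
    return max(0.0, float(rng.normal(mean_lin, sd_lin / math.sqrt(k))))


def simulate_tube(
    cfg: SimConfig, level_exponent: int, rng: np.random.Generator
) -> tuple[TubeTruth, list[TubeObservation]]:
    """Simulate one tube: inoculation, growth, and per-day COS assays."""
    grams_dry = cfg.design.inoculum_dry_g(level_exponent, cfg.sample)
    n_het = int(rng.poisson(cfg.density_het_per_g_dry * grams_dry))
    share = (
        cfg.density_cos_per_g_dry / cfg.density_het_per_g_dry
        if cfg.density_het_per_g_dry > 0
        else 0.0
    )
    n_cos = int(rng.binomial(n_het, share)) if n_het > 0 else 0
    srcb = _tube_srcb(cfg, n_cos, rng)
    k_chem = cfg.hydrolysis.k_per_h(cfg.medium_pH)

    biomass, k_bio, obs = [], [], []
    turbid = n_het >= 1
    for day in cfg.measurement_days:
        b = _biomass_mg(cfg, n_het, day)
        b_deg = b * (n_cos / n_het) if n_het > 0 else 0.0
        kb = srcb * b_deg
        biomass.append(b)
        k_bio.append(kb)
        frac = 1.0 - math.exp(-cfg.assay_duration_h * (k_chem + kb))
        residual = cfg.cos_initial_ppmv * (1.0 - frac)
        residual *= 1.0 + rng.normal(0.0, cfg.measurement_sd_pct / 100.0)
        residual = max(0.0, residual)
        obs.append(
            TubeObservation(
                level_exponent=level_exponent,
                replicate=0,  # assigned by the experiment loop
                day=day,
                turbid=turbid,
                degradation_ratio_pct=100.0
                * (1.0 - residual / cfg.cos_initial_ppmv),
                residual_ppmv=residual,
                initial_ppmv=cfg.cos_initial_ppmv,
            )
        )
    truth = TubeTruth(
        level_exponent=level_exponent,
        replicate=0,
        n_het_cells=n_het,
        n_cos_cells=n_cos,
        srcb_per_h_mg=srcb,
        biomass_trajectory=tuple(biomass),
        true_k_bio_by_day=tuple(k_bio),
    )
    return truth, obs


def simulate_experiment(
    cfg: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full design: all levels x replicates x measurement days.

    Returns ``(observations, truth)`` DataFrames.  ``observations`` is
    tubes.csv-shaped plus a ``below_detection`` column; ``truth`` is the
    per-tube ledger (kept separate so the pipeline never sees it).
    Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    obs_rows, truth_rows = [], []
    for level in cfg.design.level_exponents:
        for rep in range(1, cfg.design.tubes_per_level + 1):
            truth, obs = simulate_tube(cfg, level, rng)
            truth = replace(truth, replicate=rep)
            truth_rows.append(
                dict(
                    sample_id=cfg.sample.sample_id,
                    level_exponent=level,
                    replicate=rep,
                    n_het_cells=truth.n_het_cells,
                    n_cos_cells=truth.n_cos_cells,
                    srcb_per_h_mg=truth.srcb_per_h_mg,
                )
            )
            for o in obs:
                obs_rows.append(
                    dict(
                        sample_id=cfg.sample.sample_id,
                        level_exponent=level,
                        replicate=rep,
                        day=o.day,
                        turbid=int(o.turbid),
                        degradation_ratio_pct=o.degradation_ratio_pct,
                        residual_ppmv=o.residual_ppmv,
                        initial_ppmv=o.initial_ppmv,
                        below_detection=int(
                            o.residual_ppmv <= cfg.detection_limit_ppmv
                        ),
                    )
                )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def observations_from_frame(df: pd.DataFrame) -> list[TubeObservation]:
    """Convert a simulated observations frame into TubeObservation records."""
    return [
        TubeObservation(
            level_exponent=int(r.level_exponent),
            replicate=int(r.replicate),
            day=float(r.day),
            turbid=bool(r.turbid),
            degradation_ratio_pct=float(r.degradation_ratio_pct),
            residual_ppmv=float(r.residual_ppmv),
            initial_ppmv=float(r.initial_ppmv),
        )
        for r in df.itertuples()
    ]


def simulate_panel(
    n_samples: int,
    a: float,
    b: float,
    noise_sd_log: float,
    seed: int,
    density_range: tuple[float, float] = (1e2, 1e9),
) -> pd.DataFrame:
    """Multi-sample panel of (true density, rate constant) pairs.

    Densities are log-uniform over ``density_range``; rate constants follow
    ``y = a*x^b * 10^eps`` with ``eps ~ Normal(0, noise_sd_log)``.
    """
    if a <= 0 or b <= 0:
        raise ValidationError("power-law parameters a, b must be positive")
    rng = np.random.default_rng(seed)
    lo, hi = (math.log10(d) for d in density_range)
    x = 10.0 ** rng.uniform(lo, hi, n_samples)
    eps = rng.normal(0.0, noise_sd_log, n_samples)
    y = a * x**b * 10.0**eps
    return pd.DataFrame({"density_per_g_dry": x, "rate_constant": y})


def simulate_suspension_timecourse(
    k_per_h: float,
    times_h: tuple[float, ...] = (0.0, 4.0, 8.0, 24.0),
    c0_ppmv: float = 30.0,
    noise_sd_pct: float = 1.0,
    detection_limit_ppmv: float = 1.97,
    rng: Optional[np.random.Generator] = None,
    series_id: str = "suspension",
):
    """Headspace COS time course for a suspension decaying at rate k.

    Used to emulate the biomass-linearity experiment: a suspension with
    biomass ``B`` and specific activity ``s`` over a chemical blank ``k0``
    decays at ``k = k0 + s*B``; GC noise is multiplicative Gaussian and
    readings at or below the detection limit are flagged censored.
    """
    from .models import COSTimeCourse

    rng = rng if rng is not None else np.random.default_rng(0)
    t = np.asarray(times_h, float)
    c = c0_ppmv * np.exp(-k_per_h * t)
    c = c * (1.0 + rng.normal(0.0, noise_sd_pct / 100.0, t.size))
    c = np.maximum(c, 0.0)
    below = c <= detection_limit_ppmv
    return COSTimeCourse(
        times_h=tuple(t),
        concentrations_ppmv=tuple(c),
        below_detection=tuple(bool(x) for x in below),
        series_id=series_id,
        detection_limit_ppmv=detection_limit_ppmv,
    )
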