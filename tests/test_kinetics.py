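"""Decay fitting, hydrolysis calibration, biomass calibration, SRCB."""

import math

import numpy as np
import pytest

from cosmpn import (
    CalibrationError,
    COSTimeCourse,
    InsufficientDataError,
    SampleMetadata,
    biomass_carbon,
    calibrate_hydrolysis,
    chemical_fraction,
    compute_srcb,
    degradation_ratio,
    fit_biomass_calibration,
    fit_rate_constant,
    normalize_rate_constant,
)


def exp_course(k, times, c0=30.0, censor_below=None):
    c = [c0 * math.exp(-k * t) for t in times]
    flags = [censor_below is not None and x <= censor_below for x in c]
    return COSTimeCourse(
        times_h=tuple(times), concentrations_ppmv=tuple(c), below_detection=tuple(flags)
    )


# ---------------------------------------------------------------------------
# rate-constant fitting


@pytest.mark.parametrize(
    "k,times",
    [
        (0.0, (0, 4, 8, 24)),
        (0.5, (0, 1, 2, 4)),
        (0.3, (0, 2, 5, 8, 12)),
        (2.0, (0, 0.5, 1.0)),
    ],
)
def test_fit_exact_on_noiseless_exponential(k, times):
    fit = fit_rate_constant(exp_course(k, times))
    assert fit.k_per_h == pytest.approx(k, abs=1e-12)
    assert fit.c0_fit_ppmv == pytest.approx(30.0, rel=1e-12)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.n_points == len(times)


def test_fit_excludes_censored_points():
    # k=0.3: C(24)=0.022 ppmv, flagged below the 1.97 ppmv GC limit;
    # only flagged points are dropped from the fit
    times = (0.0, 8.0, 16.0, 24.0)
    c = tuple(30.0 * math.exp(-0.3 * t) for t in times)
    tc = COSTimeCourse(
        times_h=times, concentrations_ppmv=c,
        below_detection=(False, False, False, True),
    )
    fit = fit_rate_constant(tc)
    assert fit.n_points == 3
    assert fit.k_per_h == pytest.approx(0.3, abs=1e-12)


def test_fit_insufficient_points():
    tc = exp_course(0.3, (0, 20, 24), censor_below=5.0)  # two points censored
    with pytest.raises(InsufficientDataError):
        fit_rate_constant(tc)


def test_fit_rejects_zero_concentration():
    tc = COSTimeCourse(times_h=(0, 1, 2), concentrations_ppmv=(30, 10, 0))
    with pytest.raises(InsufficientDataError):
        fit_rate_constant(tc)


# ---------------------------------------------------------------------------
# normalization


def test_normalize_soil_matches_published_sample():
    # 4 g wet forest soil at 29.7 % water -> 2.812 g dry; k=3.093/tube
    soil = SampleMetadata(
        sample_id="KS-13", water_content=0.297, pH=5.28, mass_used_g_wet=4.0
    )
    fit = fit_rate_constant(exp_course(3.093, (0, 0.5, 1)))
    assert normalize_rate_constant(fit, soil) == pytest.approx(1.10, abs=0.005)


def test_normalize_water_per_ml():
    pond = SampleMetadata(
        sample_id="pond", sample_type="pond_water", pH=7.6, volume_ml=10.0
    )
    fit = fit_rate_constant(exp_course(0.51, (0, 1, 2)))
    assert normalize_rate_constant(fit, pond) == pytest.approx(0.051)


def test_normalize_zero_rate(design=None):
    soil = SampleMetadata(sample_id="s", water_content=0.5, mass_used_g_wet=4.0)
    fit = fit_rate_constant(exp_course(0.0, (0, 4, 8)))
    assert normalize_rate_constant(fit, soil) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# degradation ratio


@pytest.mark.parametrize(
    "c0,c_end,expected",
    [(30, 30, 0.0), (30, 18, 40.0), (30, 22.2, 26.0), (30, 0, 100.0)],
)
def test_degradation_ratio(c0, c_end, expected):
    assert degradation_ratio(c0, c_end) == pytest.approx(expected)


def test_degradation_ratio_rejects_bad_inputs():
    with pytest.raises(InsufficientDataError):
        degradation_ratio(0.0, 10.0)
    with pytest.raises(InsufficientDataError):
        degradation_ratio(30.0, -1.0)


# ---------------------------------------------------------------------------
# chemical hydrolysis


@pytest.fixture(scope="module")
def hydrolysis():
    return calibrate_hydrolysis([(7.0, 0.26), (7.5, 0.32)])


def test_calibration_constants(hydrolysis):
    # analytic 2x2 solution of the base-catalyzed model through both anchors
    assert hydrolysis.k0_per_h == pytest.approx(1.0917e-2, rel=1e-3)
    assert hydrolysis.k_oh_per_M_h == pytest.approx(1.6294e4, rel=1e-3)


def test_anchors_reproduced_exactly(hydrolysis):
    assert chemical_fraction(hydrolysis, 7.0, 24.0) == pytest.approx(0.26, abs=1e-12)
    assert chemical_fraction(hydrolysis, 7.5, 24.0) == pytest.approx(0.32, abs=1e-12)


def test_interpolated_fraction(hydrolysis):
    # independent hand computation at pH 7.25 over 24 h
    assert chemical_fraction(hydrolysis, 7.25, 24.0) == pytest.approx(0.2822, abs=2e-4)


def test_fraction_monotone_in_ph_and_duration(hydrolysis):
    phs = np.linspace(6.5, 8.0, 31)
    fracs = [chemical_fraction(hydrolysis, p, 24.0) for p in phs]
    assert all(b >= a for a, b in zip(fracs, fracs[1:]))
    durations = np.linspace(0.0, 48.0, 25)
    fracs_t = [chemical_fraction(hydrolysis, 7.2, d) for d in durations]
    assert fracs_t[0] == 0.0
    assert all(b >= a for a, b in zip(fracs_t, fracs_t[1:]))


def test_equal_anchors_mean_no_base_catalysis():
    model = calibrate_hydrolysis([(6.5, 0.26), (7.5, 0.26)])
    assert model.k_oh_per_M_h == pytest.approx(0.0, abs=1e-12)


def test_infeasible_anchors_raise():
    with pytest.raises(CalibrationError):
        calibrate_hydrolysis([(7.0, 0.32), (7.5, 0.26)])  # fraction falling with pH


# ---------------------------------------------------------------------------
# biomass calibration and SRCB


def test_biomass_calibration_exact_inversion():
    standards = (0.05, 0.5, 1.0, 3.0)
    cal = fit_biomass_calibration(standards, [2.0 * s for s in standards])
    assert biomass_carbon(4.4, cal) == pytest.approx(2.2)
    assert biomass_carbon(cal.intercept, cal) == pytest.approx(0.0, abs=1e-12)
    assert biomass_carbon(cal.slope * 1.0 + cal.intercept, cal) == pytest.approx(1.0)


def test_biomass_negative_clamped():
    cal = fit_biomass_calibration((0.5, 1.0), (6.0, 11.0))  # intercept 1
    assert biomass_carbon(0.0, cal) == 0.0


def test_srcb_arithmetic_and_flags():
    val = compute_srcb(1.40, 0.10, 0.5)
    assert val.srcb == pytest.approx(2.6)
    assert val.flag == "ok"
    assert compute_srcb(1.0, 1.0, 1.0).srcb == 0.0
    assert compute_srcb(0.5, 0.8, 1.0).flag == "negative"
    assert compute_srcb(1.0, 0.1, 0.1).flag == "low_biomass"
    with pytest.raises(InsufficientDataError):
        compute_srcb(1.0, 0.1, 0.0)


def test_srcb_scale_invariance():
    # (a*k + k_blank, k_blank, a*B) has SRCB independent of a
    ref = compute_srcb(0.9 + 0.1, 0.1, 0.45).srcb
    for a in (0.5, 2.0, 10.0):
        val = compute_srcb(a * 0.9 + 0.1, 0.1, a * 0.45)
        assert val.srcb == pytest.approx(ref)
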