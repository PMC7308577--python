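"""Positivity calling, level selection, and maximum-likelihood MPN."""

import itertools

import numpy as np
import pytest

from cosmpn import (
    AboveRangeError,
    DilutionDesign,
    RunConfig,
    SampleMetadata,
    SelectionError,
    TubeObservation,
    build_pattern,
    call_tubes,
    estimate_sample,
    mpn_confidence_interval,
    mpn_lookup_table,
    mpn_ml,
    select_levels,
    to_density,
)
from cosmpn.mpn import TubePattern

from conftest import brute_force_mpn


def three_level(positives, tubes=3, base=10):
    return TubePattern(
        levels=(0, 1, 2),
        positives=tuple(positives),
        tubes=(tubes,) * 3,
        relative_volumes=(1.0, 1.0 / base, 1.0 / base**2),
    )


# ---------------------------------------------------------------------------
# tube calling


@pytest.mark.parametrize(
    "level,rep,expect_positive,expect_first_day",
    [
        (8, 2, True, 18.0),  # transient: crosses only on day 18
        (8, 1, False, None),  # hovers at 24-29 %, never positive
        (6, 1, True, 11.0),  # ratio exactly 40: inclusive threshold
        (7, 3, True, 40.0),  # late riser, positive only on the last day
    ],
)
def test_call_tubes_canonical_cases(
    karasawa_obs, design, level, rep, expect_positive, expect_first_day
):
    calls = call_tubes(karasawa_obs, RunConfig(design=design))
    call = next(
        c for c in calls if c.level_exponent == level and c.replicate == rep
    )
    assert call.cos_positive is expect_positive
    assert call.first_positive_day == expect_first_day


def test_missing_day_is_skipped_not_zero(design):
    # a tube measured only once, above threshold, is positive
    obs = [
        TubeObservation(level_exponent=2, replicate=1, day=4.0, turbid=True),
        TubeObservation(
            level_exponent=2, replicate=1, day=11.0, degradation_ratio_pct=55.0
        ),
    ]
    calls = call_tubes(obs, RunConfig())
    assert calls[0].cos_positive and calls[0].first_positive_day == 11.0


def test_full_pattern_from_canonical_table(karasawa_obs, design):
    calls = call_tubes(karasawa_obs, RunConfig(design=design))
    pat = build_pattern(calls, design, "cos")
    assert pat.levels == tuple(range(2, 11))
    assert pat.positives == (3, 3, 3, 3, 3, 3, 1, 1, 0)
    growth = build_pattern(calls, design, "growth")
    assert growth.positives == (3, 3, 3, 3, 3, 3, 1, 1, 0)


# ---------------------------------------------------------------------------
# level selection


def make_pattern(positives, exponents):
    n = len(positives)
    return TubePattern(
        levels=tuple(exponents),
        positives=tuple(positives),
        tubes=(3,) * n,
        relative_volumes=tuple(10.0 ** -(np.array(exponents) - exponents[0])),
    )


def test_select_levels_canonical():
    pat = make_pattern((3, 3, 3, 3, 3, 3, 1, 1, 0), range(2, 11))
    window, status = select_levels(pat)
    assert window.levels == (7, 8, 9)
    assert window.positives == (3, 1, 1)
    assert status == "ok"


def test_select_levels_all_negative():
    window, status = select_levels(make_pattern((0,) * 9, range(2, 11)))
    assert window.levels == (2, 3, 4)
    assert window.positives == (0, 0, 0)
    assert status == "below_range"


def test_select_levels_folds_stray_positive():
    window, status = select_levels(make_pattern((3, 3, 1, 0, 1, 0), range(2, 8)))
    assert window.levels == (3, 4, 5)
    assert window.positives == (3, 1, 1)
    assert status == "ok"


def test_select_levels_above_range():
    window, status = select_levels(make_pattern((3, 3, 3, 3), range(2, 6)))
    assert status == "above_range"
    assert window.levels == (3, 4, 5)


def test_select_levels_window_clipped_at_top():
    # fully-positive level is second-highest: window shifts down to fit
    window, status = select_levels(make_pattern((3, 3, 3, 3, 1), range(2, 7)))
    assert window.levels == (4, 5, 6)
    assert window.positives == (3, 3, 1)
    assert status == "ok"


def test_select_levels_requires_three(design):
    with pytest.raises(SelectionError):
        select_levels(make_pattern((1, 0), (2, 3)))


# ---------------------------------------------------------------------------
# maximum likelihood


@pytest.mark.parametrize(
    "positives,expected",
    [
        ((3, 1, 1), 7.4885),
        ((3, 3, 0), 23.979),
        ((2, 1, 0), 1.4689),
        ((1, 0, 0), 0.35710),
    ],
)
def test_mpn_ml_frozen_oracle_values(positives, expected):
    # expected values computed by brute-force likelihood grid maximization
    assert mpn_ml(three_level(positives)) == pytest.approx(expected, rel=1e-3)


def test_mpn_ml_matches_brute_force_everywhere():
    for p in itertools.product(range(4), repeat=3):
        if p == (3, 3, 3) or p == (0, 0, 0):
            continue
        lam = mpn_ml(three_level(p))
        oracle = brute_force_mpn(p, (3, 3, 3), (1.0, 0.1, 0.01))
        assert lam == pytest.approx(oracle, rel=1e-4), p


def test_mpn_ml_degenerate_patterns():
    assert mpn_ml(three_level((0, 0, 0))) == 0.0
    with pytest.raises(AboveRangeError):
        mpn_ml(three_level((3, 3, 3)))


def test_mpn_ml_monotone_in_positives():
    for p in itertools.product(range(4), repeat=3):
        for i in range(3):
            q = list(p)
            q[i] += 1
            if q[i] > 3 or tuple(q) == (3, 3, 3) or p == (0, 0, 0):
                continue
            assert mpn_ml(three_level(tuple(q))) >= mpn_ml(three_level(p)) - 1e-9


def test_mpn_ml_scale_equivariant():
    base = three_level((3, 1, 1))
    lam = mpn_ml(base)
    for c in (0.1, 2.0, 37.5):
        scaled = TubePattern(
            levels=base.levels,
            positives=base.positives,
            tubes=base.tubes,
            relative_volumes=tuple(c * v for v in base.relative_volumes),
        )
        assert mpn_ml(scaled) == pytest.approx(lam / c, rel=1e-7)


# ---------------------------------------------------------------------------
# confidence interval and unit conversion


def test_ci_factor_three_tube_design():
    lo, hi = mpn_confidence_interval(1.0, DilutionDesign())
    assert hi == pytest.approx(4.5324, rel=1e-4)
    assert lo == pytest.approx(1 / 4.5324, rel=1e-4)


def test_ci_factor_shrinks_with_replication():
    many = DilutionDesign(tubes_per_level=10_000)
    lo, hi = mpn_confidence_interval(1.0, many)
    assert hi == pytest.approx(1.0, abs=0.03)


def test_to_density_examples(design, soil_sample):
    assert to_density(0.0, (7, 8, 9), design, soil_sample) == 0.0
    # soil: lambda per level-7 tube over 1e-8 g wet * dry fraction
    d = to_density(7.4885, (7, 8, 9), design, soil_sample)
    assert d == pytest.approx(7.4885e8 / 0.703, rel=1e-6)
    # water: per-mL basis, no suspension step, no dry-weight correction
    pond = SampleMetadata(
        sample_id="pond", sample_type="pond_water", pH=7.6, volume_ml=10.0
    )
    assert to_density(7.5, (1, 2, 3), design, pond) == pytest.approx(75.0)


# ---------------------------------------------------------------------------
# end-to-end


def test_canonical_experiment_end_to_end(karasawa_obs, design, soil_sample):
    """The published forest-soil table gives ~9.6e8 MPN per g dry soil for
    both COS degraders and chemoorganotrophs."""
    cos, growth = estimate_sample(karasawa_obs, design, soil_sample)
    assert cos.status == "ok"
    assert cos.pattern == (3, 1, 1)
    assert cos.selected_levels == (7, 8, 9)
    assert 9.6e8 / 1.25 <= cos.mpn_per_g_dry <= 9.6e8 * 1.25
    assert growth.mpn_per_g_dry == pytest.approx(cos.mpn_per_g_dry)
    assert cos.ci_low <= cos.mpn_per_g_dry <= cos.ci_high


def test_all_negative_experiment(design, soil_sample):
    obs = [
        TubeObservation(
            level_exponent=e, replicate=r, day=4.0, turbid=False,
            degradation_ratio_pct=20.0,
        )
        for e in design.level_exponents
        for r in (1, 2, 3)
    ]
    cos, growth = estimate_sample(obs, design, soil_sample)
    assert cos.status == "below_range" and growth.status == "below_range"
    assert cos.mpn_per_g_dry == 0.0


def test_lookup_table_has_all_patterns():
    table = mpn_lookup_table()
    assert len(table) == 64
    assert (table["status"] == "above_range").sum() == 1
    row = table[table["pattern"] == "3-1-1"].iloc[0]
    assert row["mpn_per_ref_tube"] == pytest.approx(7.4885, rel=1e-3)
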