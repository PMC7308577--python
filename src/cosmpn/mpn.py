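"""Most-probable-number estimation for the two-step COS assay.

A tube inoculated with a volume ``v`` (relative to the reference level) of
suspension containing ``lambda`` organisms per reference volume is positive
with probability ``1 - exp(-lambda*v)`` (Poisson single-hit model).  Given
positives ``p_i`` out of ``n_i`` tubes at relative volumes ``v_i``, the
maximum-likelihood density solves the score equation

    sum_i p_i v_i exp(-l v_i)/(1 - exp(-l v_i)) = sum_i (n_i - p_i) v_i,

found here by bracketed root finding (the left side minus the right is
strictly decreasing in ``l``).  This reproduces classical three-tube MPN
tables to their rounding and generalizes to any design.

Positivity itself is called in two steps: growth (turbidity) and COS
degradation (ratio >= threshold on *any* measurement day — degradation can
be transient, so a tube is positive if it ever crossed the threshold).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import AboveRangeError, SelectionError, ValidationError
from .models import DilutionDesign, RunConfig, SampleMetadata, TubeObservation

#: multiplier for the standard error of log10(MPN) in Cochran's approximation
_COCHRAN_COEF = 0.58
_Z95 = 1.96

_LAMBDA_BRACKET = (1e-6, 1e6)
_LAMBDA_RTOL = 1e-9


@dataclass(frozen=True)
class TubeCall:
    """Positivity verdicts for one tube across all its measurement days."""

    level_exponent: int
    replicate: int
    growth_positive: bool
    cos_positive: bool
    first_positive_day: Optional[float] = None


@dataclass(frozen=True)
class TubePattern:
    """Positive-tube counts per dilution level with relative inoculum volumes."""

    levels: tuple[int, ...]
    positives: tuple[int, ...]
    tubes: tuple[int, ...]
    relative_volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (
            len(self.levels)
            == len(self.positives)
            == len(self.tubes)
            == len(self.relative_volumes)
        ):
            raise ValidationError("pattern fields must have equal length")
        for p, n in zip(self.positives, self.tubes):
            if not 0 <= p <= n:
                raise ValidationError(f"positives {p} outside 0..{n}")
        v = self.relative_volumes
        if any(b >= a for a, b in zip(v, v[1:])):
            raise ValidationError("relative volumes must be strictly decreasing")

    @property
    def all_negative(self) -> bool:
        return all(p == 0 for p in self.positives)

    @property
    def all_positive(self) -> bool:
        return all(p == n for p, n in zip(self.positives, self.tubes))


@dataclass(frozen=True)
class MPNEstimate:
    """ML density with CI, the selected window, and per-gram-dry conversion."""

    sample_id: str
    target: str  # "cos" or "growth"
    pattern: tuple[int, ...]
    selected_levels: tuple[int, ...]
    lambda_per_ref_tube: Optional[float]
    mpn_per_g_dry: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    status: str  # ok | below_range | above_range


# ---------------------------------------------------------------------------
# positivity calling


def call_tubes(
    observations: Iterable[TubeObservation], cfg: RunConfig
) -> list[TubeCall]:
    """Score each tube: growth = OR of turbidity; COS = any-day ratio >= threshold.

    The threshold comparison is inclusive (a ratio of exactly 40 % counts),
    missing days are skipped, and the first day the threshold was reached is
    recorded.  Tubes with no usable measurement at all are excluded with a
    warning.
    """
    by_tube: dict[tuple[int, int], list[TubeObservation]] = {}
    for o in observations:
        by_tube.setdefault((o.level_exponent, o.replicate), []).append(o)

    calls: list[TubeCall] = []
    for (level, rep), obs in sorted(by_tube.items()):
        obs = sorted(obs, key=lambda o: o.day)
        turbid_flags = [o.turbid for o in obs if o.turbid is not None]
        ratios = [(o.day, o.ratio_pct) for o in obs if o.ratio_pct is not None]
        if not turbid_flags and not ratios:
            warnings.warn(
                f"tube {level}-{rep}: no usable measurement; excluded",
                stacklevel=2,
            )
            continue
        first_day = next(
            (d for d, r in ratios if r >= cfg.positivity_threshold_pct), None
        )
        calls.append(
            TubeCall(
                level_exponent=level,
                replicate=rep,
                growth_positive=any(turbid_flags),
                cos_positive=first_day is not None,
                first_positive_day=first_day,
            )
        )
    return calls


def build_pattern(
    calls: Sequence[TubeCall], design: DilutionDesign, which: str = "cos"
) -> TubePattern:
    """Count positive tubes per dilution level over the full design."""
    if which not in ("cos", "growth"):
        raise ValidationError(f"which must be 'cos' or 'growth', got {which!r}")
    by_level: dict[int, set[int]] = {e: set() for e in design.level_exponents}
    positives = {e: 0 for e in design.level_exponents}
    for c in calls:
        if c.level_exponent not in by_level:
            raise ValidationError(f"call at unknown level {c.level_exponent}")
        by_level[c.level_exponent].add(c.replicate)
        flag = c.cos_positive if which == "cos" else c.growth_positive
        if flag:
            positives[c.level_exponent] += 1
    for e, reps in by_level.items():
        if len(reps) != design.tubes_per_level:
            raise ValidationError(
                f"level {e}: {len(reps)} replicates present, "
                f"design requires {design.tubes_per_level}"
            )
    levels = tuple(design.level_exponents)
    return TubePattern(
        levels=levels,
        positives=tuple(positives[e] for e in levels),
        tubes=(design.tubes_per_level,) * len(levels),
        relative_volumes=tuple(design.relative_volumes(levels)),
    )


# ---------------------------------------------------------------------------
# level selection


def select_levels(pattern: TubePattern) -> tuple[TubePattern, str]:
    """Pick the three-level scoring window (classical three-tube bookkeeping).

    Window start: the highest level at which every tube is positive; the
    window is that level plus the next two.  Stray positives at levels
    beyond the window are folded into the window's last level (capped at
    n).  With no fully-positive level the three lowest levels are used;
    if the three highest levels are all fully positive the estimate is
    above range.

    Returns the restricted pattern (volumes re-referenced to the window's
    first level) and a status string.
    """
    m = len(pattern.levels)
    if m < 3:
        raise SelectionError(f"need >=3 dilution levels, have {m}")
    p, n = pattern.positives, pattern.tubes
    full = [i for i in range(m) if p[i] == n[i] and n[i] > 0]

    status = "ok"
    if pattern.all_positive or (set(full) >= {m - 3, m - 2, m - 1}):
        start, status = m - 3, "above_range"
    elif not full:
        start = 0
        if pattern.all_negative:
            status = "below_range"
    else:
        start = min(max(full), m - 3)

    idx = (start, start + 1, start + 2)
    counts = [p[i] for i in idx]
    # fold stray positives past the window into its last level, capped
    stray = sum(p[i] for i in range(start + 3, m))
    counts[2] = min(counts[2] + stray, n[idx[2]])

    window = TubePattern(
        levels=tuple(pattern.levels[i] for i in idx),
        positives=tuple(counts),
        tubes=tuple(n[i] for i in idx),
        relative_volumes=tuple(
            v / pattern.relative_volumes[start]
            for v in (pattern.relative_volumes[i] for i in idx)
        ),
    )
    if status == "ok" and window.all_negative:
        status = "below_range"
    return window, status


# ---------------------------------------------------------------------------
# maximum likelihood


def _score(lam: float, p: np.ndarray, n: np.ndarray, v: np.ndarray) -> float:
    ev = np.exp(-lam * v)
    return float(np.sum(p * v * ev / (1.0 - ev)) - np.sum((n - p) * v))


def mpn_ml(pattern: TubePattern) -> float:
    """Maximum-likelihood organisms per reference (v=1) tube.

    All-negative patterns return 0; all-positive patterns have no finite
    MLE and raise :class:`AboveRangeError`.  The score equation is solved
    by Brent's method on [1e-6, 1e6] to relative tolerance 1e-9.
    """
    if pattern.all_negative:
        return 0.0
    if pattern.all_positive:
        raise AboveRangeError(
            "all tubes positive at every level: no finite MPN estimate"
        )
    p = np.asarray(pattern.positives, float)
    n = np.asarray(pattern.tubes, float)
    v = np.asarray(pattern.relative_volumes, float)
    lo, hi = _LAMBDA_BRACKET
    return float(
        brentq(_score, lo, hi, args=(p, n, v), rtol=_LAMBDA_RTOL, xtol=1e-12)
    )


def mpn_confidence_interval(
    lam: float, design: DilutionDesign
) -> tuple[float, float]:
    """Cochran's 95% interval: multiplicative on the MPN scale.

    SE(log10 MPN) = 0.58*sqrt(log10(base)/tubes_per_level); the interval is
    ``lam * 10^(+-1.96*SE)``.  Undefined for lam <= 0.
    """
    if lam <= 0:
        return (float("nan"), float("nan"))
    se = _COCHRAN_COEF * np.sqrt(
        np.log10(design.dilution_base) / design.tubes_per_level
    )
    factor = 10.0 ** (_Z95 * se)
    return (lam / factor, lam * factor)


def to_density(
    lam: float,
    selected_levels: Sequence[int],
    design: DilutionDesign,
    sample: SampleMetadata,
) -> float:
    """Convert lambda (per reference tube of the window) to MPN per g dry (or mL).

    The reference tube is the window's lowest exponent ``e0``; it received
    ``design.inoculum_dry_g(e0, sample)`` grams dry sample (mL for waters),
    so the density is simply ``lam`` divided by that amount.
    """
    e0 = min(selected_levels)
    amount = design.inoculum_dry_g(e0, sample)
    if amount <= 0:
        raise ValidationError("non-positive inoculum amount; check design/sample")
    return lam / amount


# ---------------------------------------------------------------------------
# composition


def _estimate_one(
    pattern: TubePattern,
    design: DilutionDesign,
    sample: SampleMetadata,
    target: str,
) -> MPNEstimate:
    window, status = select_levels(pattern)
    lam: Optional[float]
    if status == "above_range":
        lam = mpn = ci_lo = ci_hi = None
    elif window.all_negative:
        lam, mpn, ci_lo, ci_hi = 0.0, 0.0, None, None
        status = "below_range"
    else:
        lam = mpn_ml(window)
        mpn = to_density(lam, window.levels, design, sample)
        lo, hi = mpn_confidence_interval(lam, design)
        scale = mpn / lam
        ci_lo, ci_hi = lo * scale, hi * scale
    return MPNEstimate(
        sample_id=sample.sample_id,
        target=target,
        pattern=window.positives,
        selected_levels=window.levels,
        lambda_per_ref_tube=lam,
        mpn_per_g_dry=mpn,
        ci_low=ci_lo,
        ci_high=ci_hi,
        status=status,
    )


def estimate_sample(
    observations: Iterable[TubeObservation],
    design: DilutionDesign,
    sample: SampleMetadata,
    cfg: Optional[RunConfig] = None,
) -> tuple[MPNEstimate, MPNEstimate]:
    """Full two-step pipeline for one sample.

    Returns the (COS-degrader, chemoorganotroph) estimate pair: calls each
    tube, builds the COS and growth patterns, selects the scoring window,
    solves the MPN likelihood, and converts to density per gram dry sample
    (per mL for waters) with Cochran confidence limits.
    """
    cfg = cfg or RunConfig(design=design)
    calls = call_tubes(observations, cfg)
    cos = _estimate_one(build_pattern(calls, design, "cos"), design, sample, "cos")
    growth = _estimate_one(
        build_pattern(calls, design, "growth"), design, sample, "growth"
    )
    return cos, growth


# ---------------------------------------------------------------------------
# lookup table


def mpn_lookup_table(design: Optional[DilutionDesign] = None) -> pd.DataFrame:
    """ML values and CIs for all three-level patterns of a three-tube design.

    Generates the classical 4^3 = 64 pattern table (``above_range`` for the
    all-positive pattern) for documentation and cross-checking against
    published three-tube MPN tables.
    """
    design = design or DilutionDesign()
    n = design.tubes_per_level
    base = design.dilution_base
    v = tuple(float(base) ** -i for i in range(3))
    rows = []
    for p in itertools.product(range(n + 1), repeat=3):
        pattern = TubePattern(
            levels=(0, 1, 2), positives=p, tubes=(n,) * 3, relative_volumes=v
        )
        if pattern.all_positive:
            rows.append(
                dict(pattern="-".join(map(str, p)), mpn_per_ref_tube=float("nan"),
                     ci_low=float("nan"), ci_high=float("nan"), status="above_range")
            )
            continue
        lam = mpn_ml(pattern)
        lo, hi = mpn_confidence_interval(lam, design)
        rows.append(
            dict(
                pattern="-".join(map(str, p)),
                mpn_per_ref_tube=lam,
                ci_low=lo,
                ci_high=hi,
                status="below_range" if lam == 0 else "ok",
            )
        )
    return pd.DataFrame(rows)
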