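# Methods

## The two-step assay and its statistical model

The assay estimates the density of culturable COS-degrading
chemoorganotrophs in an environmental sample. A suspension (3 g wet sample
in 30 mL total; water samples are used directly) is serially diluted
tenfold; 1 mL of each dilution inoculates triplicate tubes of dilute
organic medium. Step one scores chemoorganotrophic growth by turbidity.
Step two transfers 2 mL of each grown culture to a sealed tube with
30 ppmv COS and measures the fraction degraded in 24 h, repeated on
several days of the growth incubation (defaults 4, 11, 18, 40).

**Positivity.** A tube is a COS-degrader positive if its degradation ratio
reaches the threshold (default 40 %, inclusive) on *any* measured day.
The any-day rule matters: activity can be transient — a culture near the
extinction dilution may peak above threshold mid-incubation and decline —
and single-day scoring would systematically undercount. A missing
measurement is skipped, never treated as zero. The 40 % threshold sits
above the chemical-hydrolysis background (26–32 % over 24 h at the medium
pH range of 7.0–7.5, see below), so a positive indicates biological
degradation.

**MPN estimation.** Under the Poisson single-hit model, a tube receiving
relative inoculum volume `v_i` from a suspension with `λ` organisms per
reference volume is positive with probability `1 − e^(−λ v_i)`. The
log-likelihood for counts `p_i / n_i` is
`Σ_i [p_i ln(1 − e^(−λ v_i)) − (n_i − p_i) λ v_i]`, and the MLE solves the
score equation given in the README. The score is strictly decreasing in λ
for estimable patterns (some positive, not all positive), so the root is
found by Brent's method on λ ∈ [10⁻⁶, 10⁶] (relative tolerance 10⁻⁹,
deterministic). All-negative patterns return 0 (`below_range`); the
all-positive pattern has no finite MLE (`above_range`).

**Level selection.** Classical three-tube bookkeeping: the scoring window
is the highest fully-positive level plus the next two; stray positives
beyond the window are added to its last level (capped at `n`); with no
fully-positive level the three lowest levels are used; if the three highest
levels are all fully positive the result is flagged above range. The MLE is
computed on the three-level window (not the full series) to match how
published table-based MPNs are defined, making results comparable with the
field's tables; the full pattern is retained in the API for any other use.

**Confidence intervals.** Cochran's approximation:
`SE(log10 MPN) = 0.58 √(log10(base)/n)` per level, giving a multiplicative
95 % factor of 10^(1.96·SE) ≈ 4.53 for a tenfold, three-tube design. On
simulated experiments (below) the realized coverage is 0.96–0.98,
i.e. mildly conservative.

**Unit conversion.** The dilution bookkeeping takes the primary suspension
(0.1 g wet per mL) as the reference: a tube at level `e` receives
`10^−(e+1)` g wet sample, times `(1 − water content)` for grams dry.
λ per window-reference tube divided by that amount gives
MPN (g dry)⁻¹; water samples divide by the millilitres of original sample
per tube. Under this convention the canonical (3,1,1)-at-10⁷⁻⁹ pattern
gives 1.07×10⁹ MPN (g dry)⁻¹, ~11 % above the classical table value
9.6×10⁸ for the same pattern — published tables are rounded, the ML value
is exact. The alternative reading of dilution labels (level `e` = `10^−e` g
wet) would be tenfold lower and is inconsistent with the table-based value;
the adopted convention is the one that reproduces it.

## Kinetics

First-order decay `C(t) = C₀ e^(−kt)` is fitted by ordinary least squares
of `ln C` on `t` — closed-form, exact on noiseless exponentials, no
starting values or convergence concerns; a nonlinear refinement would
change nothing on well-behaved data and is deliberately out of scope.
Points at or below the GC detection limit (1.97 ppmv) are excluded from
the fit rather than imputed; with ≥2 uncensored points the estimate stays
unbiased in log space. `r²` is defined as 1 when the residual is zero
(including the 2-point case).

The chemical-hydrolysis background is modelled as base-catalyzed
first-order loss, `k_chem(pH) = k₀ + k_OH·[OH⁻]`, `[OH⁻] = 10^(pH−14)` M.
Two (pH, 24-h fraction) anchors determine both parameters by a 2×2 linear
solve; the default anchors (pH 7.0 → 26 %, pH 7.5 → 32 %) give
`k₀ = 1.092×10⁻² h⁻¹` and `k_OH = 1.63×10⁴ M⁻¹h⁻¹`. The model passes
through both anchors exactly by construction and is monotone in pH and
duration. It is a two-point calibration, not a mechanistic fit — adequate
over the buffered pH 6.5–8 range of the assay media, not beyond.

SRCB (specific rate constant normalized by biomass carbon) is
`(k_suspension − k_blank)/biomass`, in h⁻¹ (mg C)⁻¹. It is meaningful
where rate scales linearly with biomass — about 0.2–5 mg C per tube;
values computed outside that range are flagged `low_biomass`, and negative
differences are reported as-is with flag `negative` rather than clipped.
Biomass itself comes from inverting a linear glucose-carbon standard curve
(default standards 0.05, 0.5, 1, 3 mg C).

## Density–rate correlation

Across samples, per-gram rate constants relate to degrader density as
`y = a·x^b`. The fit is OLS of log10 y on log10 x (`a = 10^intercept`,
`b = slope`) with the Pearson correlation of the logs and a two-sided
t-test on n−2 df. Log-space fitting is the faithful choice because the
scatter is multiplicative and the relation is reported as a correlation
among logarithms; `r = sign(b)·√r²` by construction. Samples with
below-range (zero) MPN are excluded with a warning — their log is
undefined and only detected samples carry information about the relation.

## The synthetic-data generator

The simulator emulates the processes the estimators assume, with defaults
set to the canonical forest-soil conditions:

| parameter | default | meaning / basis |
|---|---|---|
| `density_het_per_g_dry` | 9.6×10⁸ | chemoorganotrophs per g dry (canonical sample's point estimate) |
| `density_cos_per_g_dry` | 9.6×10⁸ | COS degraders per g dry (≤ het; equal in that sample) |
| `srcb_median_per_h_mg` | 0.7 | median per-lineage activity; log-moments of a 16-isolate panel |
| `srcb_log10_sd` | 0.6 | lognormal spread of activities (panel spans ~0.03–3.3) |
| `biomass_peak_mg` | 0.5 | mg C in the 2-mL assay aliquot of a dense culture |
| `growth_lag_d`, `growth_rise_d` | 1, 6 | lag; days for a single founder to reach capacity (~1.5 decades/day) |
| `decline_rate_per_d` | 0.03 | log10 biomass decline per day past peak |
| `medium_pH` | 7.0 | buffered media; hydrolysis model calibrated at 26 %/32 % |
| `measurement_sd_pct` | 5 | multiplicative Gaussian GC noise on residual ppmv |
| `detection_limit_ppmv` | 1.97 | GC flame-photometric detection limit |

Mechanics: tube inocula are Poisson in the grams-dry delivered at each
level, with degraders a binomial subset of growers (so degraders ⊆ growers
always). A tube is turbid iff it received ≥1 grower. Biomass follows a
lag–rise–decline trajectory, piecewise linear in log biomass; because the
rise starts from the founding cell count, dilute tubes reach degrading
biomass only by later measurement days — reproducing the observed day-4
versus day-11/18 differences near extinction, and (with the activity
spread) transient positives that cross 40 % on one day only. Per-lineage
specific activities are lognormal; a tube's activity is the arithmetic
mean over its founders (neutral competition: equal biomass shares), drawn
exactly for ≤100 founders and by the normal approximation of the mean
above that. The observed 24-h fraction is
`1 − exp(−24(k_chem + SRCB·B_deg))` with `B_deg` the degrader share of
biomass, plus multiplicative noise on the residual; residuals at or below
the detection limit carry a censoring flag. Everything is reproducible
from the seed.

What the simulator does *not* capture — and hence what passing tests do
not show about real data: medium-dependent culturability (real MPN values
differ by orders of magnitude across media), competitive or antagonistic
interactions between lineages, fungal growth, pH drift over the
incubation, temperature dependence of both biology and hydrolysis (all
kinetics are at one nominal temperature), COS production by samples, and
headspace/aqueous partitioning. Simulated recovery therefore measures the
*statistical* performance of the estimator under the assay's own model,
not the accuracy of MPN as a census of in-situ populations.

Measured on 500 simulated experiments per density at 10⁴, 10⁶ and 10⁸
organisms (g dry)⁻¹: |median log10 bias| ≤ 0.13 (the residual bias is the
granularity of three-tube patterns, not a systematic error — the same
offset appears for an ideal Poisson–Bernoulli oracle) and 95 % CI coverage
0.96–0.98. Panel simulations for the power law draw densities log-uniform
over 10²–10⁹ with lognormal rate scatter.

## Numerical and degenerate-input choices

- MPN root finding: Brent on [10⁻⁶, 10⁶], rtol 10⁻⁹; bracket sign change
  guaranteed for estimable patterns.
- Degradation ratios slightly above 100 % (GC overshoot) are retained and
  flagged, not clipped; ratios outside [0, 120] are rejected. Threshold
  comparisons use the raw value.
- Missing table cells are `NA` (never zero); a tube with no usable
  measurement is excluded with a warning.
- CSV writers emit floats at 17 significant digits so write→read is the
  identity; `above_range`/`below_range` sentinels travel in the status
  column.
- Biomass inversion clamps negative carbon to 0 to guard downstream
  division; the SRCB flag records when the input was outside the linear
  range.

## Known limitations

- The three-level window convention, while standard, discards information
  at distant levels when patterns are irregular (folding mitigates this);
  an all-levels MLE is available by calling `mpn_ml` on the full pattern.
- Cochran intervals are approximate and mildly conservative; exact
  profile-likelihood intervals are not implemented.
- The hydrolysis model is a two-anchor calibration with pKw fixed at 14
  (25 °C), not a temperature-corrected rate law.
- The chemolithoautotrophic (thiosulfate-grown) variant of the assay is
  representable via `RunConfig`/`DilutionDesign` options but ships with no
  packaged example data.
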