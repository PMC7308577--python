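"""Estimate COS-degrader density from the packaged forest-soil experiment.

Loads the canonical two-step MPN table (9 tenfold dilution levels x 3
tubes, COS degradation ratios measured on days 4, 11, 18 and 40), calls
tube positivity with the inclusive >=40 % rule, and reports the
maximum-likelihood density per gram dry soil with its 95 % interval.
"""

from cosmpn import RunConfig, build_pattern, call_tubes, estimate_sample
from cosmpn.datasets import karasawa_design, karasawa_observations, karasawa_sample

design = karasawa_design()
sample = karasawa_sample()
obs = karasawa_observations()

calls = call_tubes(obs, RunConfig(design=design))
pattern = build_pattern(calls, design, "cos")
print("positives per dilution level", dict(zip(pattern.levels, pattern.positives)))

cos, growth = estimate_sample(obs, design, sample)
print(f"scoring window: levels {cos.selected_levels}, counts {cos.pattern}")
print(f"COS degraders:      {cos.mpn_per_g_dry:.3g} MPN (g dry soil)^-1 "
      f"[95% CI {cos.ci_low:.2g} - {cos.ci_high:.2g}]")
print(f"chemoorganotrophs:  {growth.mpn_per_g_dry:.3g} MPN (g dry soil)^-1")
print("Both populations coincide here: nearly every culturable organism in")
print("this soil that grows in dilute nutrient broth also degrades COS.")
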