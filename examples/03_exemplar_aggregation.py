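"""Exemplar aggregation: alignment improves as a learner accumulates instances.

Holds the linguistic modality at a well-learned 20-exemplar prototype
and incrementally aggregates visual exemplars, printing the mean
relative alignment strength (with bootstrap 95% CIs) at each count.
"""

import numpy as np

import lexalign as lx

system, _ = lx.generate_bimodal_system(lx.SyntheticSystemParams(
    n_words=30, alignment=0.9, dispersion_visual=3.0,
    dispersion_linguistic=1.0, exemplars_visual=12,
    exemplars_linguistic=20, seed=21,
))
cfg = lx.RunConfig(n_permutations=200, prototype_size=20, seed=21)
curve = lx.aggregation_curve(
    system, "visual", 8, cfg, np.random.default_rng(3), n_simulations=50
)

print("k_visual  mean_rel_strength  95% CI")
for k, m, lo, hi in zip(curve.k_values, curve.means, curve.ci_lower, curve.ci_upper):
    print(f"{k:8d}  {m:17.3f}  [{lo:.3f}, {hi:.3f}]")
print("-> averaging more visual exemplars denoises each category prototype, "
      "so the true word mapping beats an ever larger share of permuted "
      "mappings, converging to 1.0.")
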