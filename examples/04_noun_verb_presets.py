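"""Noun-like vs verb-like category structure and the 2-D aggregation grid.

Noun-like categories are visually compact and well separated; verb-like
categories are diffuse and overlapping.  With one visual exemplar and
eight linguistic exemplars per category, the noun-like system is already
well aligned while the verb-like system lags; with twenty exemplars in
both modalities, both converge.
"""

import numpy as np

import lexalign as lx

cfg = lx.RunConfig(n_permutations=200, seed=7)
for name in ("noun_like", "verb_like"):
    system, _ = lx.generate_bimodal_system(lx.preset(name, seed=42))
    grid = lx.aggregation_grid(
        system, [1, 20], [8, 20], cfg, np.random.default_rng(5), n_simulations=50
    )
    print(f"{name:10s} mean visual variability={lx.variability(system.visual).mean():5.2f}  "
          f"rel.strength(1 vis, 8 ling)={grid.means[0, 0]:.3f}  "
          f"(20, 20)={grid.means[1, 1]:.3f}")
print("-> the learning bottleneck for verb-like categories is forming a "
      "reliable category representation from diffuse exemplars, not mapping "
      "visual structure to language.")
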