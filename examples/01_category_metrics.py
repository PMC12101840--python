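"""Category structure: how variable and how discriminable are word categories?

Builds two small synthetic bimodal systems — one with compact, well
separated categories, one with diffuse, overlapping ones — and prints
the mean within-category variability and between-category
discriminability in the visual modality, plus the pooled-variance t-test
comparing them.
"""

import numpy as np

import lexalign as lx

compact, _ = lx.generate_bimodal_system(lx.SyntheticSystemParams(
    n_words=20, dispersion_visual=0.5, separation=1.5,
    exemplars_visual=10, exemplars_linguistic=10, seed=1,
))
diffuse, _ = lx.generate_bimodal_system(lx.SyntheticSystemParams(
    n_words=20, dispersion_visual=2.0, separation=0.8,
    exemplars_visual=10, exemplars_linguistic=10, seed=1,
))

var_compact = lx.variability(compact.visual)
var_diffuse = lx.variability(diffuse.visual)
disc_compact = lx.discriminability(compact.visual)
disc_diffuse = lx.discriminability(diffuse.visual)

print(f"mean visual variability    compact={var_compact.mean():.3f}  "
      f"diffuse={var_diffuse.mean():.3f}")
print(f"mean visual discriminability compact={disc_compact.mean():.3f}  "
      f"diffuse={disc_diffuse.mean():.3f}")

cmp = lx.compare_groups(var_diffuse, var_compact)
print(f"variability difference: t({cmp.degrees_of_freedom})={cmp.t_statistic:.2f}, "
      f"p={cmp.p_value:.2e}")
print("-> higher dispersion makes categories more variable (exemplars farther "
      "from their centroid); lower separation makes them less discriminable "
      "(other categories' exemplars closer to each centroid).")
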