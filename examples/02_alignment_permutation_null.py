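"""Cross-modal alignment strength against a permutation null.

Generates an aligned and an unaligned bimodal system, computes the
Spearman alignment strength between the visual and linguistic cosine
similarity matrices (over category centroids), and prints where the
true word mapping falls relative to 1,000 randomly permuted mappings.
"""

import numpy as np

import lexalign as lx
from lexalign.metrics import centroids

for label, a in (("aligned (a=0.9)", 0.9), ("unaligned (a=0.0)", 0.0)):
    system, _ = lx.generate_bimodal_system(lx.SyntheticSystemParams(
        n_words=30, alignment=a, dispersion_visual=0.8,
        dispersion_linguistic=0.8, exemplars_visual=10,
        exemplars_linguistic=10, seed=4,
    ))
    s_v = lx.cosine_similarity_matrix(centroids(system.visual), system.words)
    s_l = lx.cosine_similarity_matrix(centroids(system.linguistic), system.words)
    report = lx.alignment_report(s_v, s_l, 1000, np.random.default_rng(0))
    print(f"{label:18s} true rho={report.true_strength:+.3f}  "
          f"null mean={report.permuted_strengths.mean():+.3f}  "
          f"relative strength={report.relative_strength:.3f}")

print("-> relative strength is the fraction of permuted word mappings that "
      "align worse than the true mapping: near 1.0 when the modalities share "
      "relational structure, near uniform on [0,1] when they do not.")
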