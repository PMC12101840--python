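# Methods

## Embedding systems and conventions

An embedding system is an ordered word list with, per word, a bag of
exemplar vectors of common dimension in one modality (`linguistic` or
`visual`). A bimodal system pairs two such systems over an identical,
identically ordered word list; the order encodes the true word-to-word
mapping that the permutation analyses shuffle. Word order is always
canonicalized to the linguistic table's order when pairing; all
downstream indices refer to it.

Embeddings are used as-is: no centering or L2 normalization precedes any
distance or cosine computation. Cosine similarity is scale-invariant
per vector, and Euclidean variability/discriminability are deliberately
scale-bearing (scaling the space by *c* scales both by |c|), so
normalization would change the metrics' meaning. The `align` CLI command
exposes an explicit `--normalize` flag, off by default, for users whose
embeddings require it. Zero-norm vectors are rejected at validation
time because cosine similarity is undefined for them; tables with
non-finite entries, ragged dimensions, or missing columns fail loading
with the offending row named.

## Category structure metrics

For word *i* with exemplars `x_i1..x_iP` and centroid `c_i` (the
coordinate-wise mean):

- variability `v_i = (1/P) Σ_j ||x_ij − c_i||`
- discriminability `d_i = (1/((N−1)·K)) Σ_{j≠i} Σ_k ||x_jk − c_i||`,
  where the sum runs over every exemplar of every other word.

Exemplar counts may differ across words; each denominator uses the
actual count of contributing exemplars, which reduces to the fixed-count
form when counts are equal.

Group comparisons (e.g. noun vs verb metric distributions) use the
pooled-variance (Student) two-sample t-test with df = n1 + n2 − 2, not
Welch — the convention implied by equal-group df reporting (two groups
of 210 give df 418). Zero pooled variance with equal means returns
t = 0, p = 1; with unequal means it is an error rather than an infinite
statistic. p-values are two-sided.

## Alignment strength and the permutation null

Alignment strength is Spearman's ρ (average-rank ties) between the
N(N−1)/2 strict-upper-triangle entries of the visual and linguistic
cosine-similarity matrices over category representatives. N ≥ 3 is
required — at N = 2 the triangle is a single entry and rank correlation
is undefined; a constant triangle raises an explicit
`UndefinedAlignmentError` rather than returning NaN.

The null model permutes the word mapping: permutations of {1..N} are
sampled uniformly with replacement from all non-identity permutations
(fixed points allowed — misaligned mappings, not derangements, which is
the minimal reading of "randomly permuted"). Permuted strengths are
computed by reindexing the rows and columns of one precomputed
similarity matrix, which is mathematically identical to recomputing
cosines on the permuted vector pairing (cosine depends only on the
vectors) and costs O(N²) per permutation instead of O(N²·d). A test
asserts the equivalence exactly. Internally, the linguistic triangle is
ranked once and each permuted visual triangle is ranked and correlated
by a vectorized Pearson-of-ranks, matching `scipy.stats.spearmanr` to
1e-12.

Relative alignment strength is the fraction of permuted strengths
*strictly* below the true strength; ties count against the true mapping
(conservative; ties are measure-zero with continuous embeddings).

The per-word alignment profile — Spearman ρ between matching rows of
the two similarity matrices with the diagonal removed — is this
package's own construction for the regression feature; outputs flag it
as such. The system-level statistic is the upper-triangle ρ.

## Exemplar aggregation

Prototypes are arithmetic means of *k* exemplars sampled uniformly
without replacement. The 1-D curve fixes one modality at a
`prototype_size` (default 20) exemplar prototype and aggregates the
other *incrementally*: per simulation a without-replacement exemplar
order is drawn per word and the prototype at count *k* is the mean of
the first *k* — each simulated learning curve accumulates evidence, as
a learner would, which also reduces variance across *k*. The fixed
modality's prototype is redrawn per simulation so prototype uncertainty
propagates into the confidence intervals (a genuinely open design
point; freezing one prototype set would understate between-simulation
variance). Confidence intervals are percentile bootstrap over
simulation means, 1,000 resamples, 95% by default.

The 2-D grid varies both counts jointly, with independent prototype
draws per simulation and per cell. Grid axes accept either an integer
maximum (cells 1..max) or an explicit list of counts, so a run can
evaluate selected cells — e.g. (1 visual, 8 linguistic) and (20, 20) —
without the full grid.

Full-scale defaults (in `RunConfig`) are 1,000 permutations per
relative-strength estimate, 1,000 simulations per 1-D level, and 500
per 2-D cell. The test suite and examples run reduced sizes (typically
100–200 permutations, 40–100 simulations), chosen so that Monte Carlo
error is small against the asserted tolerances; every function takes an
explicit `n_simulations` override.

A calibration subtlety worth knowing: a single generated system retains
whatever chance alignment its category directions happened to realize,
across all exemplar-resampling simulations. The relative alignment
strength of unaligned systems is therefore uniform on [0, 1] *across
independently generated systems*, not across simulations within one
system; null-calibration checks average over replicate systems.

## Synthetic generator

Per word *i*, a shared latent direction `z_i ~ N(0, I)` in
`d_latent` dimensions. The category direction in modality *m* is
`u_i^m = M_m(√a·z_i + √(1−a)·e_i^m)` with `e_i^m ~ N(0, I)` independent
and `M_m` a random orthonormal map into the modality space. Exemplar
*j* is `s·u_i^m + σ_m·ε_ij`, `ε ~ N(0, I)` in the modality space.

- `a ∈ [0, 1]` is the cross-modal mixing weight. The √a/√(1−a) form
  keeps the direction's variance constant in `a`, so alignment varies
  without touching variability or discriminability.
- Orthonormal maps preserve angles, giving an analytic anchor: at
  `a = 1, σ = 0` the two modalities have identical similarity structure
  and alignment strength is exactly 1.
- `s > 0` scales between-category distances (drives discriminability);
  `σ_v, σ_l ≥ 0` scale within-category spread (drive variability).

Defaults (N = 40 words, d_latent = 16, modality dimension 32, 20
exemplars per word per modality) are desk-scale versions of a few
hundred categories with tens of exemplars each; dispersions near the
separation scale put single-exemplar alignment in the informative
mid-range rather than at ceiling or floor.

Presets encode the qualitative noun/verb contrast on the axes where the
two word classes differ, with the *same* mixing weight (a = 0.9):
`noun_like` has compact, separated visual categories (σ_v = 0.6,
s = 1.2); `verb_like` diffuse, overlapping ones (σ_v = 1.8, s = 0.8),
with slightly higher linguistic dispersion (1.2 vs 1.0). These values
were fixed once from that qualitative description.

What the generator does *not* emulate: the anisotropy, hubness, and
non-Gaussian cluster geometry of real vision- and language-model
embeddings, nonuniform exemplar counts, or polysemy (one word, several
visual clusters). Passing tests therefore demonstrate that the measures
behave correctly on category-clustered data with controlled ground
truth — not that any particular empirical noun/verb difference holds in
real embeddings.

The learnability generator draws word type ~ Bernoulli(0.5),
log10 frequency ~ N(3, 0.8) (per-million scale), and structure features
whose distributions shift with word type the way verb categories differ
from noun categories (more variable, less aligned, slightly less
discriminable). AoA in months is `intercept + Σ β_f · standardized(f) +
N(0, σ_noise)`, truncated to [6, 60] months; the generating coefficients
are returned alongside the table. Effects are on the
months-per-feature-SD scale; defaults (frequency −4, word type +2,
visual variability +1.5, ...) give a realistic ordering with frequency
and word type dominant.

## Age-of-acquisition regression

AoA is estimated from longitudinal proportion-knowing curves as the
midpoint of a two-parameter logistic `p(age) = 1/(1+exp(−b(age−m)))`
fitted by least squares — robust to non-monotone sampled proportions,
unlike linear interpolation. When the observed proportions never
bracket 0.5 the estimate is flagged out-of-range instead of silently
extrapolating. The estimator is equivariant under age shifts.

The regression is an XGBoost ensemble with squared-error objective at
exactly 10,000 rounds, max depth 10, learning rate 0.02, fitted
in-sample on the full table with a single thread and fixed seed
(bit-reproducible refits). The model is explanatory — the object of
interest is the attribution decomposition, not held-out prediction — so
there is no train/test split or early stopping; callers can pass any
hyperparameter overrides for cross-validation studies. log10 frequency
is the modeled transform (the standard choice in AoA work); raw
frequency is retained in the table.

Attributions are exact tree-path Shapley values computed by the tree
library itself, so local accuracy (base value + per-feature
attributions = prediction) holds to single-precision tolerance (~1e-3
months at 10,000 trees; the identity is exact in exact arithmetic).
Global importance is the mean absolute attribution per feature, reported
with the sign of the Spearman correlation between feature value and
attribution as the direction of effect.

## Reproducibility

One root seed in `RunConfig`; each pipeline stage derives an
independent substream via a CRC-keyed `SeedSequence`, so stages are
reproducible in isolation and adding a stage does not perturb the
others. All stochastic outputs are bit-reproducible under a fixed root
seed. CLI runs log config, seed, and package version to
`run_log.json`.

## Known limitations

- Rank-based alignment only; no Procrustes/CCA-style linear maps.
- The per-word alignment feature is a package construction (see above).
- Single-exemplar analyses at full scale (1,000 systems ×
  1,000 permutations) are supported but slow on one core; the df
  arithmetic is exposed separately (`pooled_df`) for design checks.
- The AoA stage accepts any per-word AoA column; it neither retrieves
  nor validates corpus provenance.
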