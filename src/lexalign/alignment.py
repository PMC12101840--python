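"""Cross-modal alignment strength and its permutation null.

Alignment strength is a second-order similarity statistic: Spearman's
rank correlation between the upper triangles of the visual and
linguistic pairwise cosine-similarity matrices of the same word set.
The permutation null shuffles the word-to-word mapping (which visual
category is named by which linguistic category); *relative alignment
strength* is the fraction of permuted mappings whose alignment strength
falls strictly below the true mapping's.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .data_model import BimodalSystem, RunConfig
from .metrics import GroupComparison, compare_groups


class UndefinedAlignmentError(ValueError):
    """Raised when a rank correlation is undefined (constant upper triangle)."""


@dataclasses.dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric N x N cosine-similarity matrix over category representatives."""

    values: np.ndarray
    words: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.words)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape must match the word list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(v < -1.0 - 1e-10) or np.any(v > 1.0 + 1e-10):
            raise ValueError("cosine similarities must lie in [-1, 1]")
        v = np.clip(v, -1.0, 1.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.words)

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclasses.dataclass(frozen=True)
class AlignmentReport:
    """True alignment strength against its permutation null."""

    true_strength: float
    permuted_strengths: np.ndarray
    relative_strength: float
    n_permutations: int

    def to_dict(self) -> dict:
        perm = self.permuted_strengths
        return {
            "true_strength": self.true_strength,
            "relative_strength": self.relative_strength,
            "n_permutations": self.n_permutations,
            "permuted_mean": float(perm.mean()),
            "permuted_sd": float(perm.std(ddof=1)) if perm.size > 1 else 0.0,
            "permuted_quantiles": {
                str(q): float(np.quantile(perm, q)) for q in (0.025, 0.25, 0.5, 0.75, 0.975)
            },
        }


def cosine_similarity_matrix(representatives: np.ndarray, words=None) -> SimilarityMatrix:
    """Pairwise cosine similarity of one representative vector per word.

    Requires N >= 3: with two words the upper triangle is a single entry
    and rank correlation downstream is undefined.
    """
    reps = np.asarray(representatives, dtype=float)
    if reps.ndim != 2 or reps.shape[0] < 3:
        raise ValueError("need at least three representative vectors")
    norms = np.linalg.norm(reps, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero-norm representative: cosine undefined")
    unit = reps / norms[:, None]
    sim = unit @ unit.T
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    if words is None:
        words = tuple(str(i) for i in range(reps.shape[0]))
    return SimilarityMatrix(values=np.clip(sim, -1.0, 1.0), words=tuple(words))


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedAlignmentError(
            "constant upper triangle: Spearman correlation undefined"
        )
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def alignment_strength(s_v: SimilarityMatrix, s_l: SimilarityMatrix) -> float:
    """Spearman rho between the strict upper triangles of the two matrices."""
    if s_v.n != s_l.n:
        raise ValueError("similarity matrices must share dimension")
    if s_v.words != s_l.words:
        raise ValueError("similarity matrices must share word order")
    return _spearman(s_v.upper_triangle(), s_l.upper_triangle())


def word_alignment_profile(s_v: SimilarityMatrix, s_l: SimilarityMatrix) -> np.ndarray:
    """Per-word alignment: Spearman rho between matching off-diagonal rows.

    This per-word decomposition is this package's own construction for
    use as a regression feature; the system-level statistic is
    :func:`alignment_strength`.
    """
    if s_v.n != s_l.n or s_v.words != s_l.words:
        raise ValueError("similarity matrices must share dimension and word order")
    n = s_v.n
    out = np.empty(n)
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        out[i] = _spearman(s_v.values[i][mask[i]], s_l.values[i][mask[i]])
    return out


def sample_permutations(
    n_words: int, n_permutations: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform non-identity permutations of range(n_words), with replacement.

    Fixed points are allowed (these are misaligned mappings, not
    derangements); only the identity itself is excluded.
    """
    if n_words < 2:
        raise ValueError("need at least two words to permute")
    identity = np.arange(n_words)
    perms = np.empty((n_permutations, n_words), dtype=np.intp)
    for i in range(n_permutations):
        perm = rng.permutation(n_words)
        while np.array_equal(perm, identity):
            perm = rng.permutation(n_words)
        perms[i] = perm
    return perms


def permuted_strengths(
    s_v: SimilarityMatrix, s_l: SimilarityMatrix, permutations: np.ndarray
) -> np.ndarray:
    """Alignment strength of each permuted word mapping.

    Permuting which visual category maps to which linguistic category is
    equivalent to reindexing the rows and columns of one similarity
    matrix: cosine similarity depends only on the vectors, so no
    similarities need recomputing.  Implemented by ranking each permuted
    upper triangle and taking the Pearson correlation of ranks
    (Spearman with average-rank ties).
    """
    if s_v.n != s_l.n:
        raise ValueError("similarity matrices must share dimension")
    perms = np.asarray(permutations, dtype=np.intp)
    if perms.ndim == 1:
        perms = perms[None, :]
    n = s_v.n
    identity = np.arange(n)
    for perm in perms:
        if not np.array_equal(np.sort(perm), identity):
            raise ValueError("invalid permutation")
    iu = np.triu_indices(n, k=1)
    tri_l = s_l.upper_triangle()
    if np.all(tri_l == tri_l[0]):
        raise UndefinedAlignmentError("constant upper triangle in s_l")
    rank_l = stats.rankdata(tri_l)
    rank_l = rank_l - rank_l.mean()
    denom_l = np.sqrt(np.sum(rank_l**2))
    tris = np.empty((perms.shape[0], tri_l.size))
    vals = s_v.values
    for i, perm in enumerate(perms):
        tris[i] = vals[np.ix_(perm, perm)][iu]
    ranks = stats.rankdata(tris, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.sum(ranks**2, axis=1)) * denom_l
    if np.any(denom == 0.0):
        raise UndefinedAlignmentError("constant upper triangle under permutation")
    return (ranks @ rank_l) / denom


def relative_alignment_strength(true_strength: float, permuted) -> float:
    """Fraction of permuted strengths strictly below the true strength."""
    perm = np.asarray(permuted, dtype=float)
    if perm.size == 0:
        raise ValueError("need at least one permuted strength")
    return float(np.mean(perm < true_strength))


def alignment_report(
    s_v: SimilarityMatrix,
    s_l: SimilarityMatrix,
    n_permutations: int,
    rng: np.random.Generator,
) -> AlignmentReport:
    """True strength, a permutation-null sample, and relative strength."""
    true = alignment_strength(s_v, s_l)
    perms = sample_permutations(s_v.n, n_permutations, rng)
    permuted = permuted_strengths(s_v, s_l, perms)
    return AlignmentReport(
        true_strength=true,
        permuted_strengths=permuted,
        relative_strength=relative_alignment_strength(true, permuted),
        n_permutations=n_permutations,
    )


@dataclasses.dataclass(frozen=True)
class SingleExemplarResult:
    """Pooled strengths over randomly sampled single-exemplar systems."""

    true_strengths: np.ndarray
    permuted_strengths: np.ndarray
    relative_strengths: np.ndarray
    comparison: GroupComparison


def single_exemplar_analysis(
    system: BimodalSystem,
    n_systems: int,
    config: RunConfig,
    rng: np.random.Generator,
) -> SingleExemplarResult:
    """Alignment of systems built from one random exemplar per word per modality.

    Draws ``n_systems`` systems; for each, one uniformly sampled exemplar
    represents each category in each modality.  Returns every system's
    true strength, the pooled permutation-null sample, per-system
    relative strengths, and the pooled-variance t comparison of true
    versus permuted strengths (df = n_systems + n_systems * n_permutations - 2).
    """
    n = system.n_words
    trues = np.empty(n_systems)
    rels = np.empty(n_systems)
    permuted_all = np.empty((n_systems, config.n_permutations))
    for s in range(n_systems):
        vis_reps = np.vstack([
            ex[rng.integers(ex.shape[0])] for ex in system.visual.exemplars
        ])
        ling_reps = np.vstack([
            ex[rng.integers(ex.shape[0])] for ex in system.linguistic.exemplars
        ])
        s_v = cosine_similarity_matrix(vis_reps, system.words)
        s_l = cosine_similarity_matrix(ling_reps, system.words)
        trues[s] = alignment_strength(s_v, s_l)
        perms = sample_permutations(n, config.n_permutations, rng)
        permuted_all[s] = permuted_strengths(s_v, s_l, perms)
        rels[s] = relative_alignment_strength(trues[s], permuted_all[s])
    pooled = permuted_all.ravel()
    comparison = compare_groups(trues, pooled)
    return SingleExemplarResult(
        true_strengths=trues,
        permuted_strengths=pooled,
        relative_strengths=rels,
        comparison=comparison,
    )
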