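"""Category structure metrics: variability, discriminability, group tests.

For a system of N word categories, *variability* of category i is the
mean Euclidean distance of its own exemplars to its centroid — how
diffuse the category is.  *Discriminability* of category i is the mean
Euclidean distance from every other category's exemplars to category
i's centroid — how far apart it sits from the rest of the system.
Both are in embedding-distance units.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import BimodalSystem, EmbeddingSystem


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    """Two-sample pooled-variance (Student) t-test result."""

    t_statistic: float
    degrees_of_freedom: int
    p_value: float
    group_means: tuple[float, float]


@dataclasses.dataclass(frozen=True)
class CategoryStructureResult:
    """Per-word structure metrics for one bimodal system."""

    words: tuple[str, ...]
    linguistic_variability: np.ndarray
    visual_variability: np.ndarray
    linguistic_discriminability: np.ndarray
    visual_discriminability: np.ndarray
    linguistic_centroids: np.ndarray  # (N, d_linguistic)
    visual_centroids: np.ndarray      # (N, d_visual)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": self.words,
                "linguistic_variability": self.linguistic_variability,
                "visual_variability": self.visual_variability,
                "linguistic_discriminability": self.linguistic_discriminability,
                "visual_discriminability": self.visual_discriminability,
            }
        )


def category_centroid(exemplars: np.ndarray) -> np.ndarray:
    """Coordinate-wise arithmetic mean of a category's exemplar vectors."""
    arr = np.asarray(exemplars, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError("need a non-empty (n, d) exemplar array")
    return arr.mean(axis=0)


def centroids(system: EmbeddingSystem) -> np.ndarray:
    """(N, d) matrix of per-word centroids."""
    return np.vstack([category_centroid(a) for a in system.exemplars])


def variability(system: EmbeddingSystem) -> np.ndarray:
    """Per-word mean Euclidean distance of exemplars to their own centroid."""
    out = np.empty(system.n_words)
    for i, arr in enumerate(system.exemplars):
        c = category_centroid(arr)
        out[i] = np.linalg.norm(arr - c, axis=1).mean()
    return out


def discriminability(system: EmbeddingSystem) -> np.ndarray:
    """Per-word mean distance from all *other* categories' exemplars to this centroid.

    With unequal exemplar counts the average runs over every exemplar of
    every other word, i.e. the denominator is the total count of other
    words' exemplars.
    """
    if system.n_words < 2:
        raise ValueError("discriminability needs at least two categories")
    cents = centroids(system)
    all_vectors = np.vstack(system.exemplars)
    owner = np.repeat(np.arange(system.n_words), system.exemplar_counts)
    out = np.empty(system.n_words)
    for i in range(system.n_words):
        others = all_vectors[owner != i]
        out[i] = np.linalg.norm(others - cents[i], axis=1).mean()
    return out


def category_structure(system: BimodalSystem) -> CategoryStructureResult:
    """All four metrics plus centroids for a paired system."""
    return CategoryStructureResult(
        words=system.words,
        linguistic_variability=variability(system.linguistic),
        visual_variability=variability(system.visual),
        linguistic_discriminability=discriminability(system.linguistic),
        visual_discriminability=discriminability(system.visual),
        linguistic_centroids=centroids(system.linguistic),
        visual_centroids=centroids(system.visual),
    )


def compare_groups(values_a, values_b) -> GroupComparison:
    """Student's pooled-variance two-sample t-test, two-sided.

    Matches the df convention n1 + n2 - 2.  Zero pooled variance with
    equal means yields t = 0, p = 1; with unequal means it is an error.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    mean_a, mean_b = a.mean(), b.mean()
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    if pooled_var == 0.0:
        if mean_a == mean_b:
            return GroupComparison(0.0, df, 1.0, (mean_a, mean_b))
        raise ValueError("zero pooled variance with unequal group means")
    t = (mean_a - mean_b) / np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupComparison(float(t), int(df), float(p), (float(mean_a), float(mean_b)))


def pooled_df(n1: int, n2: int) -> int:
    """Degrees of freedom of the pooled-variance t-test: n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least two values")
    return n1 + n2 - 2
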