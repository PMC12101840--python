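"""Exemplar-aggregation simulations: prototype formation and learning curves.

A category prototype is the arithmetic mean of k sampled exemplars,
modelling a learner who accumulates instances.  The 1-D curve holds one
modality at a well-learned prototype (default 20 exemplars) and
incrementally adds exemplars in the other; the 2-D grid varies both
counts jointly.  The outcome at every (k_visual, k_linguistic) is the
relative alignment strength of the true word mapping against its
permutation null.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .alignment import (
    cosine_similarity_matrix,
    alignment_strength,
    permuted_strengths,
    relative_alignment_strength,
    sample_permutations,
)
from .data_model import BimodalSystem, RunConfig


@dataclasses.dataclass(frozen=True)
class AggregationCurve:
    """Mean relative alignment strength per exemplar count, with bootstrap CIs."""

    aggregated_modality: str
    k_values: np.ndarray
    means: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_simulations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k_values,
                "mean_relative_strength": self.means,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "n_simulations": self.n_simulations,
            }
        )


@dataclasses.dataclass(frozen=True)
class AggregationGrid:
    """Mean relative alignment strength over (k_visual, k_linguistic) cells."""

    k_visual: np.ndarray
    k_linguistic: np.ndarray
    means: np.ndarray  # shape (len(k_visual), len(k_linguistic))
    n_simulations: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, kv in enumerate(self.k_visual):
            for j, kl in enumerate(self.k_linguistic):
                rows.append(
                    {
                        "k_visual": kv,
                        "k_linguistic": kl,
                        "mean_relative_strength": self.means[i, j],
                        "n_simulations": self.n_simulations,
                    }
                )
        return pd.DataFrame(rows)


def aggregate_prototype(
    exemplars: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean of k exemplars sampled uniformly without replacement."""
    arr = np.asarray(exemplars, dtype=float)
    if not 1 <= k <= arr.shape[0]:
        raise ValueError(f"k={k} outside [1, {arr.shape[0]}]")
    idx = rng.choice(arr.shape[0], size=k, replace=False)
    return arr[idx].mean(axis=0)


def bootstrap_ci(
    values,
    level: float,
    n_resamples: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the mean of ``values``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two values to bootstrap")
    idx = rng.integers(arr.size, size=(n_resamples, arr.size))
    means = arr[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1.0 - alpha))


def _relative_strength_of_reps(
    vis_reps: np.ndarray,
    ling_reps: np.ndarray,
    words,
    n_permutations: int,
    rng: np.random.Generator,
) -> float:
    s_v = cosine_similarity_matrix(vis_reps, words)
    s_l = cosine_similarity_matrix(ling_reps, words)
    true = alignment_strength(s_v, s_l)
    perms = sample_permutations(len(words), n_permutations, rng)
    permuted = permuted_strengths(s_v, s_l, perms)
    return relative_alignment_strength(true, permuted)


def aggregation_curve(
    system: BimodalSystem,
    aggregated_modality: str,
    max_k: int,
    config: RunConfig,
    rng: np.random.Generator,
    n_simulations: int | None = None,
) -> AggregationCurve:
    """Incremental 1-D aggregation curve for one modality.

    Per simulation, a fresh fixed-modality prototype is formed from
    ``config.prototype_size`` exemplars per word, and a without-replacement
    exemplar order is drawn per word in the aggregated modality; the
    prototype at count k is the mean of the first k exemplars in that
    order, so each simulated learning curve accumulates evidence
    incrementally rather than redrawing at every level.
    """
    if aggregated_modality not in ("visual", "linguistic"):
        raise ValueError("aggregated_modality must be 'visual' or 'linguistic'")
    n_sim = config.n_simulations_1d if n_simulations is None else n_simulations
    agg_sys = getattr(system, aggregated_modality)
    fixed_name = "linguistic" if aggregated_modality == "visual" else "visual"
    fixed_sys = getattr(system, fixed_name)
    if min(fixed_sys.exemplar_counts) < config.prototype_size:
        raise ValueError(
            f"fixed modality needs >= {config.prototype_size} exemplars per word"
        )
    if min(agg_sys.exemplar_counts) < max_k:
        raise ValueError(f"aggregated modality needs >= {max_k} exemplars per word")

    words = system.words
    rel = np.empty((n_sim, max_k))
    for s in range(n_sim):
        fixed_reps = np.vstack([
            aggregate_prototype(ex, config.prototype_size, rng)
            for ex in fixed_sys.exemplars
        ])
        orders = [rng.permutation(ex.shape[0])[:max_k] for ex in agg_sys.exemplars]
        running = np.vstack([
            ex[order[0]] for ex, order in zip(agg_sys.exemplars, orders)
        ]).astype(float)
        sums = running.copy()
        for k in range(1, max_k + 1):
            if k > 1:
                for i, (ex, order) in enumerate(zip(agg_sys.exemplars, orders)):
                    sums[i] += ex[order[k - 1]]
            agg_reps = sums / k
            if aggregated_modality == "visual":
                vis_reps, ling_reps = agg_reps, fixed_reps
            else:
                vis_reps, ling_reps = fixed_reps, agg_reps
            rel[s, k - 1] = _relative_strength_of_reps(
                vis_reps, ling_reps, words, config.n_permutations, rng
            )
    means = rel.mean(axis=0)
    lower = np.empty(max_k)
    upper = np.empty(max_k)
    for k in range(max_k):
        lower[k], upper[k] = bootstrap_ci(rel[:, k], config.ci_level, 1000, rng)
    return AggregationCurve(
        aggregated_modality=aggregated_modality,
        k_values=np.arange(1, max_k + 1),
        means=means,
        ci_lower=lower,
        ci_upper=upper,
        n_simulations=n_sim,
    )


def aggregation_grid(
    system: BimodalSystem,
    k_visual,
    k_linguistic,
    config: RunConfig,
    rng: np.random.Generator,
    n_simulations: int | None = None,
) -> AggregationGrid:
    """2-D aggregation grid over visual x linguistic exemplar counts.

    ``k_visual`` / ``k_linguistic`` may be an integer maximum (grid over
    1..max) or an explicit sequence of counts, which lets reduced-scale
    runs evaluate selected cells.  Prototypes in both modalities are
    redrawn per simulation.
    """
    kv = np.arange(1, k_visual + 1) if np.isscalar(k_visual) else np.asarray(k_visual, dtype=int)
    kl = (
        np.arange(1, k_linguistic + 1)
        if np.isscalar(k_linguistic)
        else np.asarray(k_linguistic, dtype=int)
    )
    n_sim = config.n_simulations_2d if n_simulations is None else n_simulations
    if min(system.visual.exemplar_counts) < kv.max():
        raise ValueError("insufficient visual exemplars for requested grid")
    if min(system.linguistic.exemplar_counts) < kl.max():
        raise ValueError("insufficient linguistic exemplars for requested grid")
    words = system.words
    means = np.zeros((kv.size, kl.size))
    for i, k_v in enumerate(kv):
        for j, k_l in enumerate(kl):
            acc = 0.0
            for _ in range(n_sim):
                vis_reps = np.vstack([
                    aggregate_prototype(ex, int(k_v), rng)
                    for ex in system.visual.exemplars
                ])
                ling_reps = np.vstack([
                    aggregate_prototype(ex, int(k_l), rng)
                    for ex in system.linguistic.exemplars
                ])
                acc += _relative_strength_of_reps(
                    vis_reps, ling_reps, words, config.n_permutations, rng
                )
            means[i, j] = acc / n_sim
    return AggregationGrid(
        k_visual=kv, k_linguistic=kl, means=means, n_simulations=n_sim
    )
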