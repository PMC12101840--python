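"""Synthetic bimodal embedding systems and learnability tables with ground truth.

The generator produces category-clustered Gaussian embeddings in two
modality spaces that share a controllable fraction of latent structure:

* each word has a latent direction ``z_i ~ N(0, I)`` in a shared latent
  space of dimension ``d_latent``;
* the category direction in modality m is
  ``u_i^m = M_m (sqrt(a) z_i + sqrt(1-a) e_i^m)`` with ``e_i^m`` an
  independent standard normal draw and ``M_m`` an orthonormal map into
  the modality space, so the direction's variance is constant in the
  mixing weight ``a`` and, at ``a = 1`` with zero dispersion, both
  modalities have *identical* similarity structure (orthonormal maps
  preserve angles);
* exemplar j of word i is ``s * u_i^m + sigma_m * eps_ij`` — separation
  ``s`` scales between-category distances (discriminability), the
  dispersions ``sigma_v`` / ``sigma_l`` scale within-category spread
  (variability), and ``a`` alone controls cross-modal alignment.

Learnability tables emulate a per-word feature table (frequency, word
type, structure metrics, alignment) with an age of acquisition generated
as a linear combination of known effect sizes plus Gaussian noise.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .data_model import BimodalSystem, EmbeddingSystem


@dataclasses.dataclass(frozen=True)
class SyntheticSystemParams:
    """Generator settings for one bimodal system.

    ``alignment`` in [0, 1] is the shared-latent mixing weight (1 =
    fully shared relational structure), ``separation`` > 0 scales
    between-category distances, and the two dispersions set
    within-category exemplar noise per modality.
    """

    n_words: int = 40
    d_latent: int = 16
    d_visual: int = 32
    d_linguistic: int = 32
    alignment: float = 0.85
    separation: float = 1.0
    dispersion_visual: float = 1.0
    dispersion_linguistic: float = 1.0
    exemplars_visual: int = 20
    exemplars_linguistic: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_words < 3:
            raise ValueError("n_words must be >= 3")
        if not 0.0 <= self.alignment <= 1.0:
            raise ValueError("alignment must lie in [0, 1]")
        if self.separation <= 0:
            raise ValueError("separation must be positive")
        if self.dispersion_visual < 0 or self.dispersion_linguistic < 0:
            raise ValueError("dispersions must be nonnegative")
        if self.d_latent > min(self.d_visual, self.d_linguistic):
            raise ValueError("d_latent must not exceed either modality dimension")
        if self.exemplars_visual < 1 or self.exemplars_linguistic < 1:
            raise ValueError("exemplar counts must be >= 1")


@dataclasses.dataclass(frozen=True)
class SyntheticLearnabilityParams:
    """Generator settings for a per-word learnability (AoA) table.

    Effect sizes are on the months scale per standard deviation of the
    (standardized) feature; AoA is their linear combination plus
    Gaussian noise, truncated to a plausible month range.
    """

    n_words: int = 400
    effect_log_frequency: float = -4.0
    effect_word_type: float = 2.0
    effect_visual_variability: float = 1.5
    effect_linguistic_variability: float = 0.8
    effect_alignment: float = -1.0
    effect_visual_discriminability: float = -0.4
    effect_linguistic_discriminability: float = 0.2
    noise_sd: float = 1.0
    intercept_months: float = 22.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_words < 2:
            raise ValueError("n_words must be >= 2")


def random_orthonormal_map(
    d_from: int, d_to: int, rng: np.random.Generator
) -> np.ndarray:
    """(d_to, d_from) matrix with orthonormal columns (an isometry)."""
    if d_from > d_to:
        raise ValueError("d_from must not exceed d_to")
    gauss = rng.standard_normal((d_to, d_from))
    q, r = np.linalg.qr(gauss)
    # fix signs so the map is a deterministic function of the Gaussian draw
    q *= np.sign(np.diag(r))
    return q


def generate_bimodal_system(
    params: SyntheticSystemParams, rng: np.random.Generator | None = None
) -> tuple[BimodalSystem, dict]:
    """Draw a bimodal system from the shared-latent Gaussian model.

    Returns the system and a ground-truth record of every parameter.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params
    words = tuple(f"w{i:03d}" for i in range(p.n_words))
    z = rng.standard_normal((p.n_words, p.d_latent))
    maps = {
        "visual": random_orthonormal_map(p.d_latent, p.d_visual, rng),
        "linguistic": random_orthonormal_map(p.d_latent, p.d_linguistic, rng),
    }
    sqrt_a = np.sqrt(p.alignment)
    sqrt_1a = np.sqrt(1.0 - p.alignment)
    systems = {}
    for modality, d_mod, sigma, n_ex in (
        ("visual", p.d_visual, p.dispersion_visual, p.exemplars_visual),
        ("linguistic", p.d_linguistic, p.dispersion_linguistic, p.exemplars_linguistic),
    ):
        e = rng.standard_normal((p.n_words, p.d_latent))
        directions = (sqrt_a * z + sqrt_1a * e) @ maps[modality].T
        exemplars = []
        for i in range(p.n_words):
            noise = rng.standard_normal((n_ex, d_mod))
            exemplars.append(p.separation * directions[i] + sigma * noise)
        systems[modality] = EmbeddingSystem(
            words=words, modality=modality, exemplars=tuple(exemplars)
        )
    system = BimodalSystem(linguistic=systems["linguistic"], visual=systems["visual"])
    truth = {"params": dataclasses.asdict(p)}
    return system, truth


_PRESETS = {
    # Noun-like categories: visually compact and well separated.
    "noun_like": dict(
        dispersion_visual=0.6,
        dispersion_linguistic=1.0,
        separation=1.2,
    ),
    # Verb-like categories: visually diffuse and less separated.
    "verb_like": dict(
        dispersion_visual=1.8,
        dispersion_linguistic=1.2,
        separation=0.8,
    ),
}


def preset(name: str, **overrides) -> SyntheticSystemParams:
    """Named parameter presets mimicking noun-like vs verb-like category structure.

    Both presets share the alignment mixing weight; they differ only in
    visual dispersion and category separation, the axes on which noun
    and verb categories differ.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    base = dict(
        n_words=40,
        d_latent=16,
        d_visual=32,
        d_linguistic=32,
        alignment=0.9,
        exemplars_visual=25,
        exemplars_linguistic=25,
    )
    base.update(_PRESETS[name])
    base.update(overrides)
    return SyntheticSystemParams(**base)


_FEATURES = (
    "log_frequency",
    "word_type",
    "visual_variability",
    "linguistic_variability",
    "alignment",
    "visual_discriminability",
    "linguistic_discriminability",
)


def generate_learnability_table(
    params: SyntheticLearnabilityParams, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Synthetic per-word learnability table plus its generating coefficients.

    Word type (noun = 0, verb = 1) shifts the structure-feature
    distributions the way verb categories differ from noun categories
    (more variable, less aligned), so features carry realistic
    dependence.  AoA (months) is the stated linear combination of
    standardized features plus Gaussian noise, truncated to [6, 60]
    months.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params
    n = p.n_words
    word_type = (rng.random(n) < 0.5).astype(float)
    log_frequency = rng.normal(3.0, 0.8, n)
    visual_variability = rng.normal(1.0 + 0.6 * word_type, 0.3, n).clip(min=0.05)
    linguistic_variability = rng.normal(1.0 + 0.3 * word_type, 0.3, n).clip(min=0.05)
    alignment = (rng.normal(0.5 - 0.2 * word_type, 0.15, n)).clip(-1.0, 1.0)
    visual_discriminability = rng.normal(2.0 - 0.4 * word_type, 0.4, n).clip(min=0.05)
    linguistic_discriminability = rng.normal(2.0 - 0.2 * word_type, 0.4, n).clip(min=0.05)

    table = pd.DataFrame(
        {
            "word": [f"w{i:03d}" for i in range(n)],
            "word_type": word_type,
            "frequency": np.power(10.0, log_frequency),
            "log_frequency": log_frequency,
            "visual_variability": visual_variability,
            "linguistic_variability": linguistic_variability,
            "alignment": alignment,
            "visual_discriminability": visual_discriminability,
            "linguistic_discriminability": linguistic_discriminability,
        }
    )
    effects = {
        "log_frequency": p.effect_log_frequency,
        "word_type": p.effect_word_type,
        "visual_variability": p.effect_visual_variability,
        "linguistic_variability": p.effect_linguistic_variability,
        "alignment": p.effect_alignment,
        "visual_discriminability": p.effect_visual_discriminability,
        "linguistic_discriminability": p.effect_linguistic_discriminability,
    }
    aoa = np.full(n, p.intercept_months)
    for feature, beta in effects.items():
        col = table[feature].to_numpy()
        sd = col.std()
        standardized = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        aoa = aoa + beta * standardized
    aoa = aoa + rng.normal(0.0, p.noise_sd, n)
    table["aoa_months"] = np.clip(aoa, 6.0, 60.0)
    truth = {
        "effects": effects,
        "noise_sd": p.noise_sd,
        "intercept_months": p.intercept_months,
        "features": list(_FEATURES),
    }
    return table, truth
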