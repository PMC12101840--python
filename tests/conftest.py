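import numpy as np
import pytest

import lexalign as lx


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_system(rng):
    """A random 4-word bimodal system with unequal exemplar counts."""
    words = ("ball", "dog", "run", "jump")
    d = 5
    counts_l = (3, 2, 4, 2)
    counts_v = (2, 3, 2, 5)
    ling = lx.EmbeddingSystem(
        words=words,
        modality="linguistic",
        exemplars=tuple(rng.normal(size=(c, d)) for c in counts_l),
    )
    vis = lx.EmbeddingSystem(
        words=words,
        modality="visual",
        exemplars=tuple(rng.normal(size=(c, d)) for c in counts_v),
    )
    return lx.BimodalSystem(linguistic=ling, visual=vis)


def random_system(rng, n_words=4, d=5, counts=None, modality="visual"):
    words = tuple(f"w{i}" for i in range(n_words))
    if counts is None:
        counts = rng.integers(1, 6, size=n_words)
    return lx.EmbeddingSystem(
        words=words,
        modality=modality,
        exemplars=tuple(rng.normal(size=(int(c), d)) for c in counts),
    )
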