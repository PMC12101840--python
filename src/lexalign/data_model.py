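"""Core containers for bimodal embedding systems and run configuration.

An *embedding system* holds, for an ordered list of words, a bag of
exemplar vectors per word in a single modality (linguistic contexts or
visual instances).  A *bimodal system* pairs a linguistic and a visual
system over the same ordered word list, encoding the true word-to-word
mapping that the alignment analyses permute.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

LINGUISTIC = "linguistic"
VISUAL = "visual"
_MODALITIES = (LINGUISTIC, VISUAL)


class ValidationError(ValueError):
    """Raised when an embedding table or system violates an invariant."""


@dataclasses.dataclass(frozen=True)
class EmbeddingSystem:
    """Ordered words with per-word exemplar vectors in one modality.

    Parameters
    ----------
    words
        Ordered, distinct word labels (``N >= 1``; downstream alignment
        statistics require ``N >= 3``).
    modality
        Either ``"linguistic"`` or ``"visual"``.
    exemplars
        One ``(n_i, d)`` float array per word, in word order.  Exemplar
        counts may differ across words; the dimension ``d`` may not.
    """

    words: tuple[str, ...]
    modality: str
    exemplars: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if self.modality not in _MODALITIES:
            raise ValidationError(
                f"modality must be one of {_MODALITIES}, got {self.modality!r}"
            )
        words = tuple(str(w) for w in self.words)
        if len(words) < 1:
            raise ValidationError("an embedding system needs at least one word")
        if len(set(words)) != len(words):
            raise ValidationError("word labels must be distinct")
        if len(self.exemplars) != len(words):
            raise ValidationError("one exemplar array required per word")
        arrays = []
        dim = None
        for word, arr in zip(words, self.exemplars):
            a = np.asarray(arr, dtype=float)
            if a.ndim != 2 or a.shape[0] < 1:
                raise ValidationError(
                    f"word {word!r}: exemplars must form a non-empty 2-D array"
                )
            if dim is None:
                dim = a.shape[1]
            elif a.shape[1] != dim:
                raise ValidationError(
                    f"word {word!r}: dimension {a.shape[1]} != {dim}"
                )
            if not np.all(np.isfinite(a)):
                raise ValidationError(f"word {word!r}: non-finite embedding entries")
            norms = np.linalg.norm(a, axis=1)
            if np.any(norms == 0.0):
                raise ValidationError(
                    f"word {word!r}: zero-norm exemplar (cosine undefined)"
                )
            a.setflags(write=False)
            arrays.append(a)
        if dim is None or dim < 1:
            raise ValidationError("embedding dimension must be >= 1")
        object.__setattr__(self, "words", words)
        object.__setattr__(self, "exemplars", tuple(arrays))

    @property
    def n_words(self) -> int:
        return len(self.words)

    @property
    def dim(self) -> int:
        return self.exemplars[0].shape[1]

    @property
    def exemplar_counts(self) -> tuple[int, ...]:
        return tuple(a.shape[0] for a in self.exemplars)

    def exemplars_for(self, word: str) -> np.ndarray:
        return self.exemplars[self.words.index(word)]

    def reorder(self, words: Sequence[str]) -> "EmbeddingSystem":
        """Return a copy with words reordered to the given sequence."""
        index = {w: i for i, w in enumerate(self.words)}
        try:
            order = [index[w] for w in words]
        except KeyError as exc:
            raise ValidationError(f"unknown word {exc.args[0]!r}") from exc
        if len(order) != self.n_words:
            raise ValidationError("reorder must use the full word set")
        return EmbeddingSystem(
            words=tuple(words),
            modality=self.modality,
            exemplars=tuple(self.exemplars[i] for i in order),
        )


@dataclasses.dataclass(frozen=True)
class BimodalSystem:
    """A linguistic and a visual system over one ordered word list."""

    linguistic: EmbeddingSystem
    visual: EmbeddingSystem

    def __post_init__(self) -> None:
        if self.linguistic.modality == self.visual.modality:
            raise ValidationError("the two systems must carry distinct modality tags")
        if self.linguistic.words != self.visual.words:
            raise ValidationError(
                "paired systems must share an identical, identically ordered word list"
            )

    @property
    def words(self) -> tuple[str, ...]:
        return self.linguistic.words

    @property
    def n_words(self) -> int:
        return self.linguistic.n_words


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Stochastic-stage sizes and the root seed.

    Defaults are the full-scale study settings: 1,000 permutations per
    relative-alignment estimate, 1,000 simulations per 1-D aggregation
    level, 500 per 2-D grid cell, 20-exemplar prototypes, and 95%
    bootstrap confidence intervals.
    """

    n_permutations: int = 1000
    n_simulations_1d: int = 1000
    n_simulations_2d: int = 500
    prototype_size: int = 20
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        for field in ("n_permutations", "n_simulations_1d", "n_simulations_2d",
                      "prototype_size"):
            if getattr(self, field) < 1:
                raise ValidationError(f"{field} must be >= 1")
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError("ci_level must lie in (0, 1)")

    def substream(self, stage: str) -> np.random.Generator:
        """Independent, reproducible RNG stream for a named pipeline stage."""
        stage_key = zlib.crc32(stage.encode("utf-8"))
        seq = np.random.SeedSequence(self.seed, spawn_key=(stage_key,))
        return np.random.default_rng(seq)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in {".yml", ".yaml"} else json.loads(text)
        return cls(**data)


def load_embedding_table(path: str | Path, modality: str) -> EmbeddingSystem:
    """Read a long-format embedding table (TSV or CSV) into a system.

    The header must declare ``word``, ``exemplar_id`` and ``dim_0 ..
    dim_{d-1}`` columns; each row is one exemplar.  Word order follows
    first appearance in the file.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty file") from exc
    if frame.empty:
        raise ValidationError(f"{path}: table has no rows")
    dim_cols = [c for c in frame.columns if c.startswith("dim_")]
    required = {"word", "exemplar_id"}
    missing = required - set(frame.columns)
    if missing or not dim_cols:
        raise ValidationError(
            f"{path}: missing columns {sorted(missing) + ([] if dim_cols else ['dim_*'])}"
        )
    dim_cols = sorted(dim_cols, key=lambda c: int(c.split("_", 1)[1]))
    values = frame[dim_cols].to_numpy(dtype=float)
    for row_idx in range(values.shape[0]):
        row = values[row_idx]
        if np.any(pd.isna(row)) or not np.all(np.isfinite(row)):
            raise ValidationError(
                f"{path}: row {row_idx} (word {frame['word'].iloc[row_idx]!r}) "
                "has missing or non-finite embedding entries"
            )
        if np.linalg.norm(row) == 0.0:
            raise ValidationError(
                f"{path}: row {row_idx} (word {frame['word'].iloc[row_idx]!r}) "
                "is a zero vector"
            )
    words: list[str] = []
    groups: dict[str, list[np.ndarray]] = {}
    for row_idx, word in enumerate(frame["word"].astype(str)):
        if word not in groups:
            words.append(word)
            groups[word] = []
        groups[word].append(values[row_idx])
    return EmbeddingSystem(
        words=tuple(words),
        modality=modality,
        exemplars=tuple(np.vstack(groups[w]) for w in words),
    )


def write_embedding_table(system: EmbeddingSystem, path: str | Path) -> Path:
    """Write a system in the long table format that load_embedding_table inverts."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    d = system.dim
    header = ["word", "exemplar_id"] + [f"dim_{j}" for j in range(d)]
    lines = [sep.join(header)]
    for word, arr in zip(system.words, system.exemplars):
        for j, vec in enumerate(arr):
            cells = [word, str(j)] + [repr(float(x)) for x in vec]
            lines.append(sep.join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


def pair_systems(ling: EmbeddingSystem, vis: EmbeddingSystem) -> BimodalSystem:
    """Pair two systems over the same word set, imposing the linguistic order."""
    ling_set, vis_set = set(ling.words), set(vis.words)
    if ling_set != vis_set:
        diff = sorted(ling_set.symmetric_difference(vis_set))
        raise ValidationError(f"word sets differ; symmetric difference: {diff}")
    return BimodalSystem(linguistic=ling, visual=vis.reorder(ling.words))
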