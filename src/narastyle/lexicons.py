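"""Emotion-weight and word-abstraction lexicons.

The emotion lexicon maps a word surface to a weight vector over seven
emotion categories (sadness, anxiety, anger, disgust, trust, surprise,
happiness); every vector has components in [0, 1] that sum to 1, so a
word distributes one unit of emotional association across categories.
The abstraction lexicon maps a surface to a real-valued abstraction
degree.  Both load from UTF-8 TSV files with a header row.

Lookups use the exact surface form — no lemmatization happens in the
core (an external adapter may pre-lemmatize).  A surface absent from a
lexicon is a *miss* (``None``), never a zero-weight match: unmatched
words simply carry no emotional or abstraction information and
contribute nothing to document scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Fixed category order of every emotion weight vector.
EMOTION_CATEGORIES = (
    "sadness",
    "anxiety",
    "anger",
    "disgust",
    "trust",
    "surprise",
    "happiness",
)

N_EMOTIONS = len(EMOTION_CATEGORIES)

#: Tolerance on the sum-to-one constraint when reading rows from disk.
WEIGHT_SUM_TOL = 1e-6

PathArg = Union[str, PathLike]


@dataclass(frozen=True)
class EmotionLexicon:
    """Word surface -> 7-component emotion weight vector."""

    entries: Mapping[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_items(
        cls, items: Iterable[tuple[str, Iterable[float]]], *, validate: bool = True
    ) -> "EmotionLexicon":
        entries: dict[str, np.ndarray] = {}
        for surface, weights in items:
            vec = np.asarray(list(weights), dtype=float)
            if surface in entries:
                raise ValidationError(f"duplicate emotion-lexicon surface {surface!r}")
            if validate:
                _validate_weight_vector(surface, vec)
            entries[surface] = vec
        return cls(entries=entries)

    def lookup(self, surface: str) -> Optional[np.ndarray]:
        """Weight vector for ``surface``, or ``None`` on a miss."""
        return self.entries.get(surface)

    def __contains__(self, surface: str) -> bool:
        return surface in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: PathArg) -> None:
        df = pd.DataFrame(
            [(w, *v) for w, v in self.entries.items()],
            columns=["word", *EMOTION_CATEGORIES],
        )
        df.to_csv(path, sep="\t", index=False, encoding="utf-8")


@dataclass(frozen=True)
class AbstractionLexicon:
    """Word surface -> real-valued abstraction degree."""

    entries: Mapping[str, float] = field(default_factory=dict)

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, float]]) -> "AbstractionLexicon":
        entries: dict[str, float] = {}
        for surface, degree in items:
            if surface in entries:
                raise ValidationError(f"duplicate abstraction-lexicon surface {surface!r}")
            degree = float(degree)
            if not math.isfinite(degree):
                raise ValidationError(
                    f"abstraction degree for {surface!r} is not finite: {degree!r}"
                )
            entries[surface] = degree
        return cls(entries=entries)

    def lookup(self, surface: str) -> Optional[float]:
        return self.entries.get(surface)

    def __contains__(self, surface: str) -> bool:
        return surface in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: PathArg) -> None:
        df = pd.DataFrame(
            list(self.entries.items()), columns=["word", "degree"]
        )
        df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def _validate_weight_vector(surface: str, vec: np.ndarray) -> None:
    if vec.shape != (N_EMOTIONS,):
        raise ValidationError(
            f"entry {surface!r}: expected {N_EMOTIONS} weights, got {vec.shape}"
        )
    if not np.all(np.isfinite(vec)):
        raise ValidationError(f"entry {surface!r}: non-finite weight")
    if np.any(vec < 0) or np.any(vec > 1):
        raise ValidationError(f"entry {surface!r}: weights must lie in [0, 1]")
    total = float(vec.sum())
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        raise ValidationError(
            f"entry {surface!r}: weights sum to {total:.8f}, expected 1"
        )


def load_emotion_lexicon(path: PathArg) -> EmotionLexicon:
    """Read an emotion lexicon TSV (columns: word + the 7 categories).

    Every row is validated: weights within [0, 1] and summing to 1
    (tolerance 1e-6); duplicate surfaces are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"word": str}, encoding="utf-8")
    except pd.errors.EmptyDataError:
        return EmotionLexicon.from_items([])
    expected = ["word", *EMOTION_CATEGORIES]
    if list(df.columns) != expected:
        raise ValidationError(
            f"emotion lexicon header must be {expected}, got {list(df.columns)}"
        )
    try:
        weights = df[list(EMOTION_CATEGORIES)].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric emotion weight: {exc}") from exc
    return EmotionLexicon.from_items(
        zip(df["word"].astype(str), weights.to_numpy())
    )


def load_abstraction_lexicon(path: PathArg) -> AbstractionLexicon:
    """Read an abstraction lexicon TSV (columns: word, degree)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"word": str}, encoding="utf-8")
    except pd.errors.EmptyDataError:
        return AbstractionLexicon.from_items([])
    if list(df.columns) != ["word", "degree"]:
        raise ValidationError(
            f"abstraction lexicon header must be ['word', 'degree'], got {list(df.columns)}"
        )
    if len(df) == 0:
        return AbstractionLexicon.from_items([])
    try:
        degrees = df["degree"].astype(float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"non-numeric abstraction degree: {exc}") from exc
    return AbstractionLexicon.from_items(zip(df["word"].astype(str), degrees))
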