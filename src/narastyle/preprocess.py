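"""Sentence segmentation, narrative truncation and script classification.

Narratives are short free-text stories written in Japanese.  Before any
feature is computed the raw text is (1) split into sentences at terminal
punctuation, with punctuation inside quotes or parentheses protected, and
(2) truncated to roughly the first 200 characters while keeping whole
sentences, so that documents of different lengths are comparable.

Character counting throughout the package ignores whitespace: Japanese
running text carries no spaces, so any whitespace in a response is
formatting noise, never content.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

from .exceptions import InvalidInputError, ValidationError

#: Sentence-final punctuation.  Ellipses and commas never end a sentence.
TERMINAL_PUNCTUATION = frozenset("。！？!?")

#: Bracket pairs whose interior is protected from sentence splitting.
#: An unbalanced opener protects everything to the end of the text.
BRACKET_PAIRS = {
    "「": "」",
    "『": "』",
    "（": "）",
    "(": ")",
}

#: Openers that mark quoted speech; a sentence touching such a span is
#: counted as conversational.
QUOTE_OPENERS = frozenset("「『")

#: Default truncation limit, in characters.
DEFAULT_CHAR_LIMIT = 200


class CharClass(enum.Enum):
    """Script class of a single character."""

    HIRAGANA = "hiragana"
    KATAKANA = "katakana"
    KANJI = "kanji"
    OTHER = "other"


def classify_char(ch: str) -> CharClass:
    """Classify one character into hiragana / katakana / kanji / other.

    Fixed Unicode blocks keep the script ratios bit-reproducible:
    hiragana U+3040-U+309F, katakana U+30A0-U+30FF (this includes the
    long-vowel mark ー), kanji U+4E00-U+9FFF plus the iteration mark 々
    (U+3005).  Everything else — punctuation, Latin, digits — is OTHER.
    """
    if len(ch) != 1:
        raise InvalidInputError(f"classify_char expects a single character, got {ch!r}")
    cp = ord(ch)
    if 0x3040 <= cp <= 0x309F:
        return CharClass.HIRAGANA
    if 0x30A0 <= cp <= 0x30FF:
        return CharClass.KATAKANA
    if 0x4E00 <= cp <= 0x9FFF or cp == 0x3005:
        return CharClass.KANJI
    return CharClass.OTHER


def count_chars(text: str) -> int:
    """Number of non-whitespace characters in ``text``."""
    return sum(1 for ch in text if not ch.isspace())


@dataclass(frozen=True)
class Sentence:
    """One sentence of a narrative.

    ``char_count`` excludes whitespace; ``text`` keeps every original
    character so that concatenating the sentences of a document restores
    the (stripped) source text.
    """

    index: int
    text: str
    char_count: int
    is_conversational: bool

    def __post_init__(self) -> None:
        if self.char_count < 1:
            raise InvalidInputError("sentence must contain at least one character")
        if self.char_count != count_chars(self.text):
            raise InvalidInputError("char_count inconsistent with text")


@dataclass(frozen=True)
class RawDocument:
    """A raw narrative plus optional writer metadata."""

    doc_id: str
    text: str
    age_group: Optional[str] = None
    gender: Optional[str] = None
    k10_items: Optional[tuple] = None

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise InvalidInputError(f"document {self.doc_id!r} has empty text")
        if self.k10_items is not None:
            items = tuple(self.k10_items)
            if len(items) != 10:
                raise ValidationError(
                    f"document {self.doc_id!r}: K-10 needs exactly 10 items, got {len(items)}"
                )
            if any(not (1 <= int(v) <= 5) or int(v) != v for v in items):
                raise ValidationError(
                    f"document {self.doc_id!r}: K-10 items must be integers in 1..5"
                )
            object.__setattr__(self, "k10_items", items)


def segment_sentences(text: str) -> list[Sentence]:
    """Split a narrative into sentences at terminal punctuation.

    A boundary falls immediately after 。！？! or ? unless the mark sits
    inside an open bracket span (「」『』（）()); brackets nest, and an
    unmatched opener protects the rest of the text.  Trailing material
    with no terminal mark forms a final sentence.  A sentence is
    conversational when any of its characters (including the brackets
    themselves) lies inside a 「…」 or 『…』 quotation.
    """
    stripped = text.strip()
    if not stripped:
        raise InvalidInputError("cannot segment empty or whitespace-only text")

    sentences: list[Sentence] = []
    stack: list[str] = []  # expected closers, innermost last
    quote_depth = 0  # how many of the open spans are quotations
    start = 0
    conversational = False

    for i, ch in enumerate(stripped):
        if stack and ch == stack[-1]:
            conversational = conversational or quote_depth > 0
            closer = stack.pop()
            if closer in ("」", "』"):
                quote_depth -= 1
            continue
        if ch in BRACKET_PAIRS:
            stack.append(BRACKET_PAIRS[ch])
            if ch in QUOTE_OPENERS:
                quote_depth += 1
            conversational = conversational or quote_depth > 0
            continue
        conversational = conversational or quote_depth > 0
        if ch in TERMINAL_PUNCTUATION and not stack:
            chunk = stripped[start : i + 1]
            sentences.append(
                Sentence(
                    index=len(sentences),
                    text=chunk,
                    char_count=count_chars(chunk),
                    is_conversational=conversational,
                )
            )
            start = i + 1
            conversational = False

    if start < len(stripped):
        chunk = stripped[start:]
        sentences.append(
            Sentence(
                index=len(sentences),
                text=chunk,
                char_count=count_chars(chunk),
                is_conversational=conversational,
            )
        )
    return sentences


def truncate_narrative(
    sentences: Sequence[Sentence], limit: int = DEFAULT_CHAR_LIMIT
) -> list[Sentence]:
    """Keep the longest sentence prefix consistent with the character limit.

    With cumulative non-whitespace character counts ``C_j``, the kept
    prefix is the largest ``m`` with ``C_m <= limit`` (clause a); the next
    sentence is additionally kept when its overshoot past the limit is
    strictly smaller than the shortfall the prefix leaves
    (``C_{m+1} - limit < limit - C_m``, clause b) — the cut closest to the
    limit wins, and ties drop the extra sentence.  If even the first
    sentence exceeds the limit it is kept alone, so no narrative ever
    truncates to nothing.  Sentences are never modified, so the result may
    exceed ``limit`` under clause (b).
    """
    sentences = list(sentences)
    if not sentences:
        raise InvalidInputError("cannot truncate an empty sentence list")
    if limit < 1:
        raise InvalidInputError("limit must be >= 1")

    cumulative = 0
    m = 0
    for sent in sentences:
        if cumulative + sent.char_count > limit:
            break
        cumulative += sent.char_count
        m += 1

    if m == 0:
        return [sentences[0]]
    if m < len(sentences):
        overshoot = cumulative + sentences[m].char_count - limit
        shortfall = limit - cumulative
        if overshoot < shortfall:
            return sentences[: m + 1]
    return sentences[:m]
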