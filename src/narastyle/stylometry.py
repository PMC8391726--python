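"""Per-document stylometric measures.

One annotated narrative yields a fixed vector of style metrics:

* script composition — hiragana / katakana / kanji ratios over all
  non-whitespace characters;
* lexical — type-token ratio, content-word ratio, the verb-to-modifier
  ratio (verbs over adjectives + adverbs + conjunctions, as used for
  authorship attribution of Japanese text), proper-noun ratio;
* word abstraction — maximum and top-5 mean abstraction degree of the
  words found in the abstraction lexicon;
* sentence level — sentence count, mean sentence length in characters,
  fraction of conversational (quoted-speech) sentences;
* syntax — mean dependency-tree depth, mean chunks (bunsetsu) per
  sentence, mean words per chunk;

plus the seven-category emotion profile from :mod:`narastyle.sentiment`.

The annotations (POS tags, chunk spans, chunk dependency heads) come in
with the document; no morphological analyzer or parser runs here.
Metrics that are undefined for a document — e.g. the verb-to-modifier
ratio when the document has no adjective, adverb or conjunction, or
abstraction statistics when no word hits the lexicon — are NaN, and the
group comparison later drops such documents from the affected row only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InvalidInputError, InvalidStructureError
from .lexicons import EMOTION_CATEGORIES, AbstractionLexicon, EmotionLexicon
from .preprocess import RawDocument, Sentence

#: Part-of-speech tag set the core understands.  Adapters map analyzer
#: tag sets (e.g. IPAdic) onto these.
POS_TAGS = ("NOUN", "PROPN", "VERB", "ADJ", "ADV", "CONJ", "OTHER")

#: Tags counted as content words: nouns (proper nouns are nouns), verbs,
#: adjectives and adverbs.
CONTENT_TAGS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})

#: Denominator tags of the verb-to-modifier ratio.
MODIFIER_TAGS = frozenset({"ADJ", "ADV", "CONJ"})

#: Head value marking the root chunk of a sentence.
ROOT = -1


@dataclass(frozen=True)
class Token:
    """One word token with its POS tag and owning chunk."""

    surface: str
    pos: str
    chunk_index: int

    def __post_init__(self) -> None:
        if not self.surface:
            raise InvalidInputError("token surface must be non-empty")
        if self.pos not in POS_TAGS:
            raise InvalidInputError(f"unknown POS tag {self.pos!r}")


@dataclass(frozen=True)
class Chunk:
    """A bunsetsu: a half-open token span [start, end) and its head chunk.

    ``head`` is the index of the chunk this one depends on, or ``ROOT``.
    """

    start: int
    end: int
    head: int


@dataclass(frozen=True)
class ChunkedSentence:
    """A sentence with its tokens, chunk spans and dependency links."""

    sentence: Sentence
    tokens: tuple[Token, ...]
    chunks: tuple[Chunk, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        object.__setattr__(self, "chunks", tuple(self.chunks))
        validate_chunk_structure(self.tokens, self.chunks)


def validate_chunk_structure(
    tokens: Sequence[Token], chunks: Sequence[Chunk]
) -> None:
    """Check that chunks partition the tokens and heads form a rooted tree."""
    if not tokens:
        raise InvalidStructureError("sentence has no tokens")
    if not chunks:
        raise InvalidStructureError("sentence has no chunks")
    pos = 0
    for i, chunk in enumerate(chunks):
        if chunk.start != pos or chunk.end <= chunk.start:
            raise InvalidStructureError(
                f"chunk {i} span [{chunk.start}, {chunk.end}) does not continue "
                f"the partition at token {pos}"
            )
        pos = chunk.end
    if pos != len(tokens):
        raise InvalidStructureError(
            f"chunk spans cover {pos} tokens but sentence has {len(tokens)}"
        )
    for tok in tokens:
        if not (0 <= tok.chunk_index < len(chunks)):
            raise InvalidStructureError(
                f"token {tok.surface!r} references chunk {tok.chunk_index}"
            )
    roots = [i for i, c in enumerate(chunks) if c.head == ROOT]
    if len(roots) != 1:
        raise InvalidStructureError(f"expected exactly one root chunk, found {len(roots)}")
    n = len(chunks)
    for i, chunk in enumerate(chunks):
        if chunk.head != ROOT and not (0 <= chunk.head < n):
            raise InvalidStructureError(f"chunk {i} has out-of-range head {chunk.head}")
    # cycle check: every chunk must reach the root
    for i in range(n):
        seen = set()
        j = i
        while j != ROOT:
            if j in seen:
                raise InvalidStructureError(f"dependency cycle through chunk {i}")
            seen.add(j)
            j = chunks[j].head


@dataclass(frozen=True)
class AnnotatedDocument:
    """A truncated narrative with sentence-level annotations."""

    raw: RawDocument
    sentences: tuple[ChunkedSentence, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sentences", tuple(self.sentences))
        if not self.sentences:
            raise InvalidInputError("annotated document must have >= 1 sentence")

    @property
    def tokens(self) -> list[Token]:
        return [tok for cs in self.sentences for tok in cs.tokens]

    @property
    def text(self) -> str:
        """Post-truncation text: the concatenated kept sentences."""
        return "".join(cs.sentence.text for cs in self.sentences)


@dataclass(frozen=True)
class FeatureVector:
    """All per-document metrics, in the order the comparison report uses."""

    hiragana_ratio: float
    katakana_ratio: float
    kanji_ratio: float
    ttr: float
    content_word_ratio: float
    mvr: float
    propn_ratio: float
    abstraction_max: float
    abstraction_top5_mean: float
    emotion: tuple[float, ...]
    n_sentences: int
    mean_sentence_len: float
    conversational_pct: float
    mean_tree_depth: float
    mean_chunks_per_sentence: float
    mean_words_per_chunk: float

    def as_dict(self) -> dict[str, float]:
        """Flatten into metric-name -> value (emotion split per category)."""
        d = {
            "hiragana_ratio": self.hiragana_ratio,
            "katakana_ratio": self.katakana_ratio,
            "kanji_ratio": self.kanji_ratio,
            "ttr": self.ttr,
            "content_word_ratio": self.content_word_ratio,
            "mvr": self.mvr,
            "propn_ratio": self.propn_ratio,
            "abstraction_max": self.abstraction_max,
            "abstraction_top5_mean": self.abstraction_top5_mean,
        }
        for cat, value in zip(EMOTION_CATEGORIES, self.emotion):
            d[f"emotion_{cat}"] = value
        d.update(
            n_sentences=float(self.n_sentences),
            mean_sentence_len=self.mean_sentence_len,
            conversational_pct=self.conversational_pct,
            mean_tree_depth=self.mean_tree_depth,
            mean_chunks_per_sentence=self.mean_chunks_per_sentence,
            mean_words_per_chunk=self.mean_words_per_chunk,
        )
        return d


#: Row order of the comparison report: script, lexical, abstraction,
#: emotion, sentence-level, then syntax metrics.
METRIC_ORDER = tuple(
    ["hiragana_ratio", "katakana_ratio", "kanji_ratio", "ttr",
     "content_word_ratio", "mvr", "propn_ratio",
     "abstraction_max", "abstraction_top5_mean"]
    + [f"emotion_{cat}" for cat in EMOTION_CATEGORIES]
    + ["n_sentences", "mean_sentence_len", "conversational_pct",
       "mean_tree_depth", "mean_chunks_per_sentence", "mean_words_per_chunk"]
)


def _char_codes(text: str) -> np.ndarray:
    """Code points of the non-whitespace characters of ``text``."""
    compact = "".join(text.split())
    return np.frombuffer(compact.encode("utf-32-le"), dtype=np.uint32)


def char_type_ratios(doc: AnnotatedDocument) -> tuple[float, float, float]:
    """Hiragana, katakana and kanji fractions of the document's characters.

    The residual (1 - sum) is the OTHER fraction: punctuation, brackets,
    Latin letters, digits.
    """
    codes = _char_codes(doc.text)
    total = codes.size
    if total == 0:
        raise InvalidInputError("document has no non-whitespace characters")
    hira = int(np.count_nonzero((codes >= 0x3040) & (codes <= 0x309F)))
    kata = int(np.count_nonzero((codes >= 0x30A0) & (codes <= 0x30FF)))
    kanji = int(
        np.count_nonzero(((codes >= 0x4E00) & (codes <= 0x9FFF)) | (codes == 0x3005))
    )
    return hira / total, kata / total, kanji / total


def lexical_ratios(doc: AnnotatedDocument) -> tuple[float, float, float, float]:
    """Type-token ratio, content-word ratio, verb-to-modifier ratio and
    proper-noun ratio.

    The verb-to-modifier ratio is NaN when the document contains no
    adjective, adverb or conjunction (undefined, not infinite).
    """
    tokens = doc.tokens
    if not tokens:
        raise InvalidInputError("document has no tokens")
    n = len(tokens)
    ttr = len({t.surface for t in tokens}) / n
    content = sum(1 for t in tokens if t.pos in CONTENT_TAGS) / n
    propn = sum(1 for t in tokens if t.pos == "PROPN") / n
    verbs = sum(1 for t in tokens if t.pos == "VERB")
    modifiers = sum(1 for t in tokens if t.pos in MODIFIER_TAGS)
    mvr = verbs / modifiers if modifiers else math.nan
    return ttr, content, mvr, propn


def abstraction_stats(
    doc: AnnotatedDocument, lexicon: AbstractionLexicon
) -> tuple[float, float]:
    """Maximum and top-5 mean abstraction degree over lexicon hits.

    Token-based: every occurrence of a matched word contributes.  With
    fewer than five hits the top-5 mean is the mean of all hits; with no
    hits both statistics are NaN.
    """
    if not doc.tokens:
        raise InvalidInputError("document has no tokens")
    hits = [d for d in (lexicon.lookup(t.surface) for t in doc.tokens) if d is not None]
    if not hits:
        return math.nan, math.nan
    hits.sort(reverse=True)
    top = hits[:5]
    return hits[0], sum(top) / len(top)


def sentence_stats(doc: AnnotatedDocument) -> tuple[int, float, float]:
    """Sentence count, mean sentence length (chars) and conversational share."""
    sents = [cs.sentence for cs in doc.sentences]
    n = len(sents)
    mean_len = sum(s.char_count for s in sents) / n
    conv = sum(1 for s in sents if s.is_conversational) / n
    return n, mean_len, conv


def tree_depth(chunks: Sequence[Chunk]) -> int:
    """Depth of a sentence's chunk dependency tree.

    Depth of the root chunk is 1; the sentence depth is the longest
    chunk-to-root path, so a single-chunk sentence has depth 1.
    """
    n = len(chunks)
    best = 0
    for i in range(n):
        steps = 1
        j = i
        while chunks[j].head != ROOT:
            j = chunks[j].head
            steps += 1
            if steps > n:
                raise InvalidStructureError("dependency cycle")
        best = max(best, steps)
    return best


def syntax_stats(doc: AnnotatedDocument) -> tuple[float, float, float]:
    """Mean tree depth, mean chunks per sentence, mean words per chunk.

    Words per chunk is averaged over all chunks of the document, chunks
    per sentence over sentences.
    """
    depths = []
    chunk_counts = []
    chunk_sizes = []
    for cs in doc.sentences:
        depths.append(tree_depth(cs.chunks))
        chunk_counts.append(len(cs.chunks))
        chunk_sizes.extend(c.end - c.start for c in cs.chunks)
    return (
        float(np.mean(depths)),
        float(np.mean(chunk_counts)),
        float(np.mean(chunk_sizes)),
    )


def extract_features(
    doc: AnnotatedDocument,
    emotion_lexicon: EmotionLexicon,
    abstraction_lexicon: AbstractionLexicon,
    *,
    emotion_mode: str = "normalized",
) -> FeatureVector:
    """Assemble the full per-document feature vector.

    Deterministic for fixed inputs; any sub-metric that is undefined for
    this document comes through as NaN.
    """
    from .sentiment import emotion_profile  # local import: avoid cycle

    hira, kata, kanji = char_type_ratios(doc)
    ttr, content, mvr, propn = lexical_ratios(doc)
    abs_max, abs_top5 = abstraction_stats(doc, abstraction_lexicon)
    profile = emotion_profile(doc, emotion_lexicon, mode=emotion_mode)
    n_sent, mean_len, conv = sentence_stats(doc)
    depth, chunks_per_sent, words_per_chunk = syntax_stats(doc)
    return FeatureVector(
        hiragana_ratio=hira,
        katakana_ratio=kata,
        kanji_ratio=kanji,
        ttr=ttr,
        content_word_ratio=content,
        mvr=mvr,
        propn_ratio=propn,
        abstraction_max=abs_max,
        abstraction_top5_mean=abs_top5,
        emotion=tuple(float(x) for x in profile),
        n_sentences=n_sent,
        mean_sentence_len=mean_len,
        conversational_pct=conv,
        mean_tree_depth=depth,
        mean_chunks_per_sentence=chunks_per_sent,
        mean_words_per_chunk=words_per_chunk,
    )
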