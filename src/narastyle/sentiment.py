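"""Weighted-lexicon emotion profile of a document.

Each lexicon word carries one unit of emotional mass distributed over
seven categories.  The document profile sums those vectors over the
tokens that hit the lexicon and divides by a denominator chosen by
``mode``:

``normalized`` (default)
    divide by the number of matched tokens; the seven components then
    sum to 1 and the profile reads as "how the story's emotional mass
    distributes across categories".  This is the scale on which the
    reference group summaries of this analysis are reported (their seven
    category means sum to ~1.000).

``per_all_words``
    divide by the total token count; the components sum to the matched
    fraction, reading as "how much of the story's vocabulary carries
    each emotion".

With zero matched tokens the profile is all-NaN and the document is
flagged by the comparison stage (dropped from emotion rows only).
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidInputError
from .lexicons import N_EMOTIONS, EmotionLexicon
from .stylometry import AnnotatedDocument

MODES = ("normalized", "per_all_words")


def emotion_profile(
    doc: AnnotatedDocument, lexicon: EmotionLexicon, mode: str = "normalized"
) -> np.ndarray:
    """Seven-component emotion profile of ``doc``.

    Token-based: each occurrence of a matched word contributes its weight
    vector once.  Token order is irrelevant, and tokens missing from the
    lexicon contribute nothing (under ``normalized`` they leave the
    profile unchanged).
    """
    if mode not in MODES:
        raise InvalidInputError(f"mode must be one of {MODES}, got {mode!r}")
    tokens = doc.tokens
    if not tokens:
        raise InvalidInputError("document has no tokens")

    total = np.zeros(N_EMOTIONS)
    matched = 0
    for tok in tokens:
        vec = lexicon.lookup(tok.surface)
        if vec is not None:
            total += vec
            matched += 1
    if matched == 0:
        return np.full(N_EMOTIONS, np.nan)
    denom = matched if mode == "normalized" else len(tokens)
    return total / denom


def matched_token_count(doc: AnnotatedDocument, lexicon: EmotionLexicon) -> int:
    """Number of tokens of ``doc`` with an emotion-lexicon hit."""
    return sum(1 for tok in doc.tokens if tok.surface in lexicon)
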