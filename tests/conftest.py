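from pathlib import Path

import pytest

from narastyle import (
    AnnotatedDocument,
    Chunk,
    ChunkedSentence,
    EmotionLexicon,
    AbstractionLexicon,
    GeneratorConfig,
    RawDocument,
    ROOT,
    Sentence,
    Token,
    generate_corpus,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


def make_sentence(index, text, conversational, tokens, chunks):
    """Build a ChunkedSentence from terse (surface, pos, chunk) specs."""
    from narastyle import count_chars

    sent = Sentence(
        index=index,
        text=text,
        char_count=count_chars(text),
        is_conversational=conversational,
    )
    toks = tuple(Token(surface=s, pos=p, chunk_index=c) for s, p, c in tokens)
    chs = tuple(Chunk(start=a, end=b, head=h) for a, b, h in chunks)
    return ChunkedSentence(sentence=sent, tokens=toks, chunks=chs)


@pytest.fixture
def handworked_doc() -> AnnotatedDocument:
    """Two-sentence document with every metric computable by hand.

    S1 "猫が速く走る。": tokens 猫/NOUN が/OTHER | 速く/ADV 走る/VERB,
    chunk 0 -> chunk 1 (root); depth 2.
    S2 "「ネコだ」。": tokens ネコ/NOUN だ/OTHER in one root chunk;
    conversational; depth 1.
    """
    s1 = make_sentence(
        0,
        "猫が速く走る。",
        False,
        [("猫", "NOUN", 0), ("が", "OTHER", 0), ("速く", "ADV", 1), ("走る", "VERB", 1)],
        [(0, 2, 1), (2, 4, ROOT)],
    )
    s2 = make_sentence(
        1,
        "「ネコだ」。",
        True,
        [("ネコ", "NOUN", 0), ("だ", "OTHER", 0)],
        [(0, 2, ROOT)],
    )
    raw = RawDocument(doc_id="hand", text="猫が速く走る。「ネコだ」。")
    return AnnotatedDocument(raw=raw, sentences=(s1, s2))


@pytest.fixture
def handworked_emotion_lexicon() -> EmotionLexicon:
    return EmotionLexicon.from_items(
        [
            ("猫", (0, 0, 0, 0, 0, 0.4, 0.6)),
            ("ネコ", (0, 0, 0, 0, 1, 0, 0)),
        ]
    )


@pytest.fixture
def handworked_abstraction_lexicon() -> AbstractionLexicon:
    return AbstractionLexicon.from_items([("猫", 1.5), ("走る", 2.5), ("だ", 0.5)])


@pytest.fixture(scope="session")
def default_bundle():
    """One default-condition synthetic corpus (21 + 31 narratives, seed 11)."""
    return generate_corpus(GeneratorConfig(seed=11))
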