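"""Per-document stylometric measures, including a full hand-worked fixture."""

import math

import numpy as np
import pytest

from narastyle import (
    AnnotatedDocument,
    Chunk,
    ChunkedSentence,
    InvalidStructureError,
    METRIC_ORDER,
    RawDocument,
    ROOT,
    abstraction_stats,
    char_type_ratios,
    extract_features,
    lexical_ratios,
    sentence_stats,
    syntax_stats,
    tree_depth,
)
from narastyle.lexicons import AbstractionLexicon, EmotionLexicon

from conftest import make_sentence


def single_sentence_doc(text, tokens, chunks, conversational=False):
    cs = make_sentence(0, text, conversational, tokens, chunks)
    return AnnotatedDocument(
        raw=RawDocument(doc_id="d", text=text), sentences=(cs,)
    )


class TestCharTypeRatios:
    def test_mixed_script_counts(self):
        doc = single_sentence_doc(
            "ねこがすき。", [("ねこがすき", "NOUN", 0)], [(0, 1, ROOT)]
        )
        hira, kata, kanji = char_type_ratios(doc)
        assert hira == pytest.approx(5 / 6)
        assert kata == 0.0 and kanji == 0.0

    def test_single_class_text(self):
        doc = single_sentence_doc("ネコ", [("ネコ", "NOUN", 0)], [(0, 1, ROOT)])
        assert char_type_ratios(doc) == (0.0, 1.0, 0.0)

    def test_ratios_plus_other_sum_to_one(self, default_bundle):
        for doc in default_bundle.documents[:10]:
            hira, kata, kanji = char_type_ratios(doc)
            assert 0 <= hira <= 1 and 0 <= kata <= 1 and 0 <= kanji <= 1
            assert hira + kata + kanji <= 1 + 1e-12


class TestLexicalRatios:
    def test_direct_counting(self):
        doc = single_sentence_doc(
            "猫が好きだ。",
            [("猫", "NOUN", 0), ("が", "OTHER", 0), ("好き", "ADJ", 1), ("だ", "OTHER", 1)],
            [(0, 2, 1), (2, 4, ROOT)],
        )
        ttr, content, mvr, propn = lexical_ratios(doc)
        assert ttr == 1.0
        assert content == 0.5
        assert mvr == 0.0  # 0 verbs / 1 adjective
        assert propn == 0.0

    def test_unit_counts(self):
        doc = single_sentence_doc(
            "速く走る。", [("走る", "VERB", 0), ("速く", "ADV", 0)], [(0, 2, ROOT)]
        )
        assert lexical_ratios(doc)[2] == 1.0

    def test_repeated_token_lowers_ttr(self):
        doc = single_sentence_doc(
            "猫" * 10 + "。", [("猫", "NOUN", 0)] * 10, [(0, 10, ROOT)]
        )
        assert lexical_ratios(doc)[0] == pytest.approx(0.1)

    def test_mvr_missing_when_no_modifiers(self):
        doc = single_sentence_doc(
            "走る。", [("走る", "VERB", 0)], [(0, 1, ROOT)]
        )
        assert math.isnan(lexical_ratios(doc)[2])


class TestAbstractionStats:
    def lex(self, mapping):
        return AbstractionLexicon.from_items(mapping.items())

    def make_doc(self, degrees_by_word):
        tokens = [(w, "NOUN", 0) for w in degrees_by_word]
        return single_sentence_doc(
            "".join(degrees_by_word) + "。", tokens, [(0, len(tokens), ROOT)]
        )

    def test_fewer_than_five_hits_mean_of_all(self):
        words = {"一": 3.0, "二": 2.0, "三": 1.0}
        mx, top5 = abstraction_stats(self.make_doc(words), self.lex(words))
        assert mx == 3.0
        assert top5 == pytest.approx(2.0)

    def test_top_five_selection(self):
        words = {w: float(d) for w, d in zip("一二三四五六", range(1, 7))}
        mx, top5 = abstraction_stats(self.make_doc(words), self.lex(words))
        assert mx == 6.0
        assert top5 == pytest.approx((2 + 3 + 4 + 5 + 6) / 5)

    def test_no_hits_is_missing(self):
        doc = self.make_doc({"一": 0.0})
        mx, top5 = abstraction_stats(doc, self.lex({"別": 9.9}))
        assert math.isnan(mx) and math.isnan(top5)


class TestSentenceStats:
    def test_direct_arithmetic(self):
        s1 = make_sentence(0, "あ" * 10, False, [("あ", "OTHER", 0)], [(0, 1, ROOT)])
        s2 = make_sentence(1, "い" * 20, False, [("い", "OTHER", 0)], [(0, 1, ROOT)])
        doc = AnnotatedDocument(
            raw=RawDocument(doc_id="d", text="x"), sentences=(s1, s2)
        )
        assert sentence_stats(doc) == (2, 15.0, 0.0)

    def test_all_dialogue(self):
        s = make_sentence(0, "「やあ」。", True, [("やあ", "OTHER", 0)], [(0, 1, ROOT)])
        doc = AnnotatedDocument(raw=RawDocument(doc_id="d", text="x"), sentences=(s,))
        assert sentence_stats(doc)[2] == 1.0


def chain_chunks(heads):
    return tuple(Chunk(start=i, end=i + 1, head=h) for i, h in enumerate(heads))


class TestTreeDepth:
    def test_three_chunk_chain(self):
        # A -> B -> C(root): longest path 3
        assert tree_depth(chain_chunks([1, 2, ROOT])) == 3

    def test_single_chunk(self):
        assert tree_depth(chain_chunks([ROOT])) == 1

    def test_star_topology(self):
        assert tree_depth(chain_chunks([3, 3, 3, ROOT])) == 2

    def test_cycle_detected(self):
        sent = make_sentence(
            0, "ある。", False,
            [("あ", "OTHER", 0), ("る", "OTHER", 1)],
            [(0, 1, 1), (1, 2, ROOT)],
        )
        with pytest.raises(InvalidStructureError):
            ChunkedSentence(
                sentence=sent.sentence,
                tokens=sent.tokens,
                chunks=chain_chunks([1, 0]),  # no root, cyclic
            )

    def test_matches_brute_force_enumeration_on_random_trees(self):
        # oracle: recursive longest root-to-leaf path over the children map
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 9))
            heads = [ROOT] * n
            perm = rng.permutation(n)
            for i in range(1, n):
                heads[int(perm[i])] = int(perm[int(rng.integers(0, i))])
            children = {i: [] for i in range(n)}
            root = next(i for i in range(n) if heads[i] == ROOT)
            for i, h in enumerate(heads):
                if h != ROOT:
                    children[h].append(i)

            def longest(node):
                kids = children[node]
                return 1 + (max(longest(k) for k in kids) if kids else 0)

            assert tree_depth(chain_chunks(heads)) == longest(root)


class TestSyntaxStats:
    def test_two_sentence_means(self, handworked_doc):
        depth, chunks_per_sent, words_per_chunk = syntax_stats(handworked_doc)
        assert depth == pytest.approx(1.5)  # depths 2 and 1
        assert chunks_per_sent == pytest.approx(1.5)
        assert words_per_chunk == pytest.approx(2.0)  # sizes 2, 2, 2


class TestExtractFeatures:
    def test_handworked_fixture_all_fields(
        self, handworked_doc, handworked_emotion_lexicon, handworked_abstraction_lexicon
    ):
        fv = extract_features(
            handworked_doc, handworked_emotion_lexicon, handworked_abstraction_lexicon
        )
        # 13 characters: hiragana が,く,る,だ; katakana ネ,コ; kanji 猫,速,走
        assert fv.hiragana_ratio == pytest.approx(4 / 13)
        assert fv.katakana_ratio == pytest.approx(2 / 13)
        assert fv.kanji_ratio == pytest.approx(3 / 13)
        assert fv.ttr == 1.0  # 6 distinct surfaces / 6 tokens
        assert fv.content_word_ratio == pytest.approx(4 / 6)
        assert fv.mvr == pytest.approx(1.0)  # 1 verb / 1 adverb
        assert fv.propn_ratio == 0.0
        assert fv.abstraction_max == pytest.approx(2.5)
        assert fv.abstraction_top5_mean == pytest.approx((2.5 + 1.5 + 0.5) / 3)
        # matched tokens 猫 and ネコ: mean of (…,0.4,0.6) and (…,1,0,0)
        np.testing.assert_allclose(fv.emotion, (0, 0, 0, 0, 0.5, 0.2, 0.3))
        assert fv.n_sentences == 2
        assert fv.mean_sentence_len == pytest.approx(6.5)
        assert fv.conversational_pct == 0.5
        assert fv.mean_tree_depth == pytest.approx(1.5)
        assert fv.mean_chunks_per_sentence == pytest.approx(1.5)
        assert fv.mean_words_per_chunk == pytest.approx(2.0)

    def test_composition_identity_and_determinism(
        self, handworked_doc, handworked_emotion_lexicon, handworked_abstraction_lexicon
    ):
        a = extract_features(
            handworked_doc, handworked_emotion_lexicon, handworked_abstraction_lexicon
        )
        b = extract_features(
            handworked_doc, handworked_emotion_lexicon, handworked_abstraction_lexicon
        )
        assert a == b
        assert char_type_ratios(handworked_doc) == (
            a.hiragana_ratio, a.katakana_ratio, a.kanji_ratio
        )
        assert lexical_ratios(handworked_doc)[0] == a.ttr

    def test_as_dict_covers_metric_order(
        self, handworked_doc, handworked_emotion_lexicon, handworked_abstraction_lexicon
    ):
        fv = extract_features(
            handworked_doc, handworked_emotion_lexicon, handworked_abstraction_lexicon
        )
        d = fv.as_dict()
        assert set(d) == set(METRIC_ORDER)
        assert len(METRIC_ORDER) == 22

    def test_single_sentence_chunk_token_consistency(self, default_bundle):
        # for one-sentence documents: chunks/sentence x token-weighted
        # words/chunk equals the token count
        emo = EmotionLexicon.from_items([])
        for doc in default_bundle.documents[:20]:
            first = doc.sentences[0]
            one = AnnotatedDocument(raw=doc.raw, sentences=(first,))
            _, chunks_per_sent, _ = syntax_stats(one)
            sizes = [c.end - c.start for c in first.chunks]
            assert chunks_per_sent * (sum(sizes) / len(sizes)) == pytest.approx(
                len(first.tokens)
            )
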