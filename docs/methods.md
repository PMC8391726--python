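# Methods

This note documents the models, conventions and numerical choices
behind `narastyle`, and what the synthetic corpus does and does not
establish about real narrative data.

## Preprocessing

**Sentence segmentation.**  A sentence boundary falls immediately after
any of 。！？! ? that is not inside an open bracket span.  Protected
pairs are 「」『』（）(); spans nest, and an unbalanced opener protects
to the end of the text.  This is the minimal conventional reading of
"split at punctuation, except inside parentheses": ellipses, commas and
middle dots never split.  A sentence is *conversational* when any of
its characters (brackets included) lies inside a 「…」 or 『…』
quotation, the Japanese conventions for quoted speech.  Trailing text
without a terminal mark forms a final sentence, so segmentation is
total: concatenating the sentences reproduces the (stripped) input.

**Character counting** excludes whitespace everywhere — Japanese
running text is unspaced, so whitespace in a crowdsourced response is
formatting noise.  All lengths, ratios and the truncation limit count
non-whitespace characters.

**Truncation.**  With cumulative sentence lengths C_j and limit L = 200,
keep the largest prefix with C_m ≤ L, and additionally the next
sentence iff C_{m+1} − L < L − C_m (strict: the cut closest to the
limit wins, ties drop).  Two deliberate conventions:

* *Floor rule:* if even the first sentence exceeds L it is kept alone —
  the pipeline never discards a whole narrative at this stage.
* *Short texts pass through unchanged*, since the ≥200-character
  writing instruction may not have been enforced upstream; truncation
  is then the identity, which also makes the operation idempotent in
  general (proved as a property test).

**Script classification** uses fixed Unicode blocks so ratios are
bit-reproducible: hiragana U+3040–U+309F; katakana U+30A0–U+30FF
(including the long-vowel mark ー); kanji U+4E00–U+9FFF plus the
iteration mark 々.  Everything else is OTHER, so the four fractions
partition every character.

## Metrics

* The core consumes annotations (POS per token, bunsetsu chunk spans,
  chunk dependency heads) and never runs a morphological analyzer or
  parser itself; any tagger whose output is mapped onto
  {NOUN, PROPN, VERB, ADJ, ADV, CONJ, OTHER} can feed it.
* Type-token ratio uses distinct *surface forms* (no lemmatization —
  none is part of the defined procedure).
* Content words are nouns (proper nouns included), verbs, adjectives
  and adverbs.
* The verb-to-modifier ratio is implemented exactly as defined for this
  analysis — verbs over adjectives + adverbs + conjunctions — not the
  classical stylometric MVR (modifiers over verbs).  It is NaN
  (missing, not infinite) when the denominator is zero.
* Abstraction statistics are token-based over lexicon hits: maximum
  degree, and the mean of the five largest (of all hits when fewer
  than five); both NaN with zero hits.
* Dependency-tree depth counts chunks with the root at depth 1, so a
  one-chunk sentence has depth 1; the document value is the mean over
  sentences.  Depth is computed and reported although the emulated
  study's published comparison table has no depth row.
* Words per chunk is averaged over all chunks of the document; chunks
  per sentence over sentences.  Means of ratios are not ratios of
  means, so no cross-identity between these is asserted except in the
  single-sentence case (tested).
* All "descriptive statistics" metrics are reported as means, matching
  one value per table cell in the emulated report.

## Emotion profile

Each emotion-lexicon word carries a weight vector over (sadness,
anxiety, anger, disgust, trust, surprise, happiness) with components in
[0,1] summing to 1 (validated at load, tolerance 1e-6).  The document
profile sums matched tokens' vectors and divides by either the matched
count (`normalized`, default) or the total token count
(`per_all_words`).  The default is `normalized` because the reference
group means this package reconciles against sum to ≈1.000 across the
seven categories, which is only consistent with per-matched-token
normalization; the literal "ratio relative to all words" reading is
retained as the second mode and recorded in every output header.
Tokens absent from the lexicon are misses, not zero-weight matches:
they change `per_all_words` denominators but leave `normalized`
profiles untouched.  Zero matches yield an all-NaN profile; the
comparison stage then drops that document from emotion rows only.

## Grouping and comparison

K-10: ten items scored 1–5, total 10–50, higher distress iff
total ≥ cutoff (default 30, boundary inclusive; configurable).

For each of the 22 metrics the two groups are compared with a
two-sample t test, t signed as mean(higher) − mean(lower).  Welch
(Satterthwaite df) is the default; the pooled equal-variance variant is
always available because reconciliation against the reference table
shows its printed df (n1+n2−2) and its happiness t (2.657) are
consistent only with the pooled formula, despite the table's footnote
naming Welch — the package takes no side and records the variant in
every output.  A related printed oddity: the reference happiness t is
negative although the higher-distress mean is larger; `narastyle`
reports signs strictly under its own convention.  Documents missing a
metric are excluded from that row only (listwise per metric, n
reported per row).  No multiplicity correction is applied by default,
mirroring the emulated analysis (~20 tests); a Benjamini–Hochberg
column is available behind a flag as the better practice.

p-values come from `scipy.stats.t`; the t statistics and Satterthwaite
df are computed in closed form here (the summary-statistic entry point
and the rounding-interval reconciliation need them explicitly), and the
test suite cross-checks them against `scipy.stats.ttest_ind` and frozen
hand-computed values to 1e-10.

**Rounding-interval reconciliation.**  Published tables print means and
SDs to 3 decimals, hiding the unrounded values in a ±0.0005 box.  The
t statistic is monotone in the mean difference and each SD, so its
extrema over the box are at the 16 corners; the resulting interval is
the set of t values any data consistent with the printout could give.
The acceptance suite shows the pooled interval for the reference
happiness summaries (21, 0.134, 0.049 vs 31, 0.109, 0.018) contains the
printed 2.657 while the Welch interval does not.

## Synthetic corpus generator

The generator emulates the *statistical* shape of the emulated study's
corpus, not Japanese grammar.  Defaults are the study conditions and
are fixed once:

| parameter | default | rationale |
|---|---|---|
| group sizes | 21 / 31 | the emulated youth cohort |
| sentences per story | Poisson(6.8) | reference sentence counts ~6.6–7.4 |
| tokens per sentence | Poisson(21), min 1 | ~8.2 chunks/sentence × ~2.6 words/chunk |
| word length | 1 + Poisson(0.6) chars | short morpheme-like units; ~33-char sentences |
| chunk size | 1 + Poisson(1.57) tokens | mean ≈ 2.57 words per bunsetsu |
| POS mix | N .145, PN .01, V .04, ADJ .04, ADV .035, CONJ .025, OTH .705 | content ratio ≈ 0.27, V/(ADJ+ADV+CONJ) ≈ 0.4, proper nouns ≈ 1% |
| script mix | hira .62 / kata .05 / kanji .33 | mixed-script narrative text |
| conversational rate | 0.05 | reference conversational share 4–6% |
| emotion match rate | 0.30 | a minority of tokens carry emotional load |
| minimum story length | 200 chars | the writing instruction |
| K-10 totals | uniform 30–50 / 10–29 | consistent with group by construction |

**Emotion mechanism.**  Each document draws a propensity vector
p ~ Dirichlet(α_group).  Each matched token is a fresh lexicon word
with weights ~ Dirichlet(κ·p), κ = 200, so the normalized document
profile is the mean of ~34–43 such vectors ≈ p with a small
within-document noise term.  The group concentration vectors are
α = A·μ with μ the seven reference category means and A set from the
happiness moments, A = p(1−p)/σ² − 1: A ≈ 47.3 (higher, σ = 0.049) and
A ≈ 298.7 (lower, σ = 0.018).  The generated between-group happiness
shift therefore *is* the reference effect (≈0.7 pooled SD); the null
configuration simply sets both groups to the lower-distress Dirichlet.

**Surfaces.**  Non-matched tokens come from a shared 35-word filler
pool (giving type-token ratios near 0.55 and repeated words for
abstraction hits); matched tokens encode a global counter into script
sub-ranges disjoint from the filler ranges, so lexicon membership is
exact, collision-free, and every emotion word is unique.  Abstraction
degrees ~ Normal(2.0, 0.5) cover half the filler pool.  Chunk
dependency trees are uniform random recursive trees over chunks,
exercising depths from chains to stars.  A single `numpy` Generator
seeded from the config drives everything: identical configs give
bit-identical corpora, features and comparison tables (tested).

**What passing tests do and do not show.**  The corpus validates the
pipeline's bookkeeping (segmentation closure, truncation bounds,
normalization, determinism) and its statistical calibration (type-I
error, power against an independent Monte-Carlo oracle of the emotion
mechanism).  It does not validate linguistic claims: surfaces are not
words, POS tags are independent of surfaces, a pool word may recur
under different tags, and no discourse or topical structure exists.
Conclusions about real narratives require real annotated corpora and
the real emotion/abstraction dictionaries, loaded through the same
readers.

## Problem sizes and numerical details

* Monte-Carlo calibration tests use 1000 replicate corpora at the
  default 52-document size (~2 minutes each on one CPU); the power
  oracle uses 2000 vectorized replicates of the emotion mechanism with
  a representative matched-token count of 34 (truncation keeps ~200
  characters of ~1.75-character tokens, 30% matched).  The type-I band
  [0.03, 0.07] is ±3 binomial SEs around 0.05 at 1000 replicates.
* Lexicon weight validation tolerance is 1e-6 on file load (printed
  precision), 1e-9 for in-memory profile sums.
* The comparison table contains 22 rows — the 21 rows of the emulated
  report plus tree depth.
* Ties in the truncation rule drop the extra sentence (strict
  inequality); ties among abstraction degrees are irrelevant (order
  statistics only).
* The bundled `tests/data/*_fixture.tsv` lexicons are synthetic
  fixtures for the readers; they do not reproduce any real dictionary.

## Known limitations

* No lemmatization, named-entity recognition, negation handling or
  contextual sentiment; the emotion profile is a bag-of-matched-tokens
  summary.
* Real-parser adapters (MeCab/CaboCha-style) are out of scope; the
  JSONL annotation block is the interoperability point.
* The K-10 is a screening instrument; nothing here supports clinical
  claims, and the group comparison is purely descriptive statistics.
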