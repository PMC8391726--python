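# narastyle

Stylometric and lexicon-based sentiment analysis of short Japanese
narratives, with comparison of writers grouped by psychological
distress.

## The problem

Internalizing mental illness in young people often goes undetected, and
screening that relies on autobiographical self-disclosure works poorly
in cultures where self-disclosure is uncommon.  One alternative is to
ask people to write a short *imaginative* story (an introduction of at
least 200 Japanese characters to an imagined narrative), screen them
separately with the Kessler Psychological Distress Scale (K-10), and
ask whether measurable properties of the story — style, vocabulary,
emotional vocabulary — differ between writers above and below the
severe-distress cutoff.  `narastyle` implements that analysis as a
reusable, tested pipeline for researchers in computational mental-health
text analytics.

## The method

For each narrative the pipeline:

1. **Segments** the raw text into sentences at terminal punctuation
   (。！？!?), never splitting inside quotes or parentheses
   (「」『』（）()), and marks quoted-speech sentences as conversational.
2. **Truncates** to the first ~200 characters while preserving whole
   sentences: keep the longest prefix with cumulative length
   C<sub>m</sub> ≤ 200, plus the next sentence iff its overshoot is
   strictly smaller than the remaining gap
   (C<sub>m+1</sub> − 200 < 200 − C<sub>m</sub>).
3. **Extracts 22 metrics** from token/chunk/dependency annotations:
   hiragana/katakana/kanji ratios; type-token ratio; content-word
   ratio; verb-to-modifier ratio V/(ADJ+ADV+CONJ); proper-noun ratio;
   maximum and top-5 mean word-abstraction degree; sentence count, mean
   sentence length, conversational share; mean dependency-tree depth,
   chunks (bunsetsu) per sentence, words per chunk; and a seven-category
   emotion profile (sadness, anxiety, anger, disgust, trust, surprise,
   happiness) from a weighted emotion lexicon in which each word's
   weights sum to 1.  By default the profile is normalized by the
   number of matched tokens, so the seven components sum to 1.
4. **Groups** writers by K-10 total (10 items, 1–5 each; total ≥ 30 ⇒
   higher distress) and compares every metric between groups with a
   two-sample t test — Welch (default) or pooled, t signed as
   mean(higher) − mean(lower) — producing a publication-style table of
   group means, SDs, t, df and p.

Because the original crowdsourced narratives are not publicly
deposited, the package ships a seeded synthetic-corpus generator that
reproduces the study conditions (21 higher- vs 31 lower-distress
writers, ≥200-character mixed-script stories with POS/chunk/dependency
annotations, and a happiness-profile shift of mean 0.134 SD 0.049 vs
mean 0.109 SD 0.018 between groups), so the full pipeline is testable
and demonstrable offline.  See `docs/methods.md` for the generative
model and its limitations.

## Worked example

```bash
narastyle run-all --seed 5 --out-dir demo
```

prints

```
52 narratives analyzed; happiness: 0.137 (0.057) vs 0.115 (0.017), t=1.726, df=22.5, p=0.098
```

and writes `demo/corpus.jsonl` (52 annotated narratives, one JSON
record per line), the two lexicon TSVs, `demo/features.csv` (the
52 × 22 feature matrix) and `demo/comparison.csv` — a 22-row table
whose header records the run configuration:

```
# cutoff: 30
# emotion_mode: normalized
# n_documents: 52
# seed: 5
# test_variant: welch
# truncation_limit: 200
metric,n_high,mean_high,sd_high,n_low,mean_low,sd_low,t,df,p
hiragana_ratio,21,0.576,0.049,31,0.616,0.050,-2.835,43.613,0.007
...
```

The quoted line reads: across this synthetic corpus the 21
higher-distress writers' mean happiness share of emotional mass was
0.137 (SD 0.057) against 0.115 (SD 0.017) for the 31 lower-distress
writers; a Welch test gives t = 1.726 on 22.5 df, p = 0.098 — a
happiness shift of the built-in default size is present but, at these
group sizes, detected in only about half of replicate corpora (the
test suite measures this power by simulation).  A companion
`comparison_full.csv` keeps full floating-point precision.

The same steps are available separately (`narastyle simulate`,
`narastyle extract`, `narastyle compare`) for use with real annotated
corpora and real lexicons in the documented JSONL/TSV formats, and the
whole pipeline is importable as a library (`narastyle.generate_corpus`,
`narastyle.extract_features`, `narastyle.compare_groups`, ...).

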