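# Methods

This note documents the models, conventions and numerical choices behind
`phonalign`, and what the synthetic-data tests do and do not establish.

## Transcription

Lexicons are plain-text CMUDict 0.7b dialect: `;;;` comments, entries
`WORD  P1 P2 ...`, alternates `WORD(2)`, decoding falling back to Latin-1
(the real CMUDict file has a few non-UTF-8 comment bytes). Lexical stress
digits (0–2 on vowels) are stripped on load; nothing downstream uses
stress, so transcription is invariant to pre-stripping (tested).

Tokenisation uppercases, splits on whitespace, and trims the edge
punctuation `.,;:!?"()-` while keeping internal apostrophes (CMUDict has
entries like `IT'S`). Numerals and abbreviations are not expanded; they
surface as unresolved-word errors, as does any out-of-vocabulary token.
The intended workflow for nonsense responses is a per-session override
lexicon in the same format, consulted before the main lexicon.

**Pronunciation variants.** When a word has alternates (`LIVE` L-IH-V /
L-AY-V, `THE` DH-AH / DH-IY), the first listed pronunciation is used.
This is a package convention, not a fact about listeners; overrides can
force any variant per word. The alignment-uniqueness sentence example is
therefore stated under first-pronunciation transcriptions.

The bundled fixture lexicon (~100 words) covers all 39 phonemes and every
word used in examples and tests; the full CMUDict can be loaded by path.

## Alignment model

States and costs. A match is a substitution in the zero tier, so the DP
has three states (substitution/match, insertion, deletion), indexed by the
operation that produced the cell — the history-dependent analogue of
affine-gap alignment. Default costs (cost units are arbitrary; only
ratios matter):

| operation | after sub | after ins | after del | at start |
|---|---|---|---|---|
| insertion | 1.5 | 1.0 | 1.5 | 1.0 |
| deletion | 1.5 | 1.5 | 1.0 | 1.0 |
| sub: vowel–consonant | 5.0 | 5.1 | 5.5 | 5.0 |
| sub: consonant–consonant | 1.75 | 1.85 | 2.25 | 1.75 |
| sub: same-manner consonant | 1.3 | 1.4 | 1.8 | 1.3 |
| sub: similar consonant | 1.2 | 1.3 | 1.7 | 1.2 |
| sub: vowel–vowel | 0.9 | 0.8 | 1.4 | 0.9 |
| sub: similar vowel | 0.65 | 0.75 | 1.15 | 0.65 |
| match | 0.0 | 0.1 | 0.2 | 0.0 |

The sequence start charges the no-switch column, which makes an all-gap
alignment of an empty string against a length-n string cost exactly n (a
tested base case) and reproduces every intermediate cell value of the
worked fun/thin example. The vowel–vowel after-insertion value 0.8 breaks
the otherwise uniform +0.1-after-insertion pattern; it is retained as
configured rather than "corrected".

*Similar* vowels differ in at most one of the four vowel features
(configurable). *Similar* consonants default to the eight voicing-cognate
pairs {P,B} {T,D} {K,G} {F,V} {S,Z} {SH,ZH} {CH,JH} {TH,DH}: this makes
F↔V a preferred confusion while leaving TH↔F and S↔TH in the same-manner
tier, consistent with the worked examples. The pair list is part of the
costs YAML and fully configurable.

**Feature table.** The shipped table encodes vowels by height, contour,
place and length, and consonants by nasality, manner, voicing, affrication
(frication noise), sibilance and place. It contains feature-identical
pairs (TH/V, DH/F, SH/S, ZH/Z) — the feature space is deliberately coarser
than the inventory, and the table is an editable CSV for users who prefer
a different featureisation.

**Enumeration and ties.** The DP is filled backwards (optimal completion
cost per cell and state) and alignments are generated by a forward
depth-first walk that tries substitution/match, then deletion, then
insertion; co-optimal alignments therefore stream out in a stable,
documented order and `align` returns the canonical first. Cost ties are
detected with absolute tolerance 1e-9 (all table costs are short exact
decimals, so true ties are exact in binary sums well below that
tolerance). Enumeration truncates at a cap (default 1000) with an
`exhausted` flag instead of erroring. Correctness of both the MED and the
complete co-optimal set is tested against an exhaustive edit-script
enumerator on thousands of short pairs.

## Scoring

Per pair and phoneme: TP = matches, FN = deletions plus substituted
stimulus phonemes, FP = insertions plus substituted response phonemes;
F1 = 2TP/(2TP+FP+FN). Two conservation laws hold by construction and are
tested: Σ(TP+FN) = stimulus length, Σ(TP+FP) = response length.

"Averaged F1" over a session is ambiguous, so both conventions are
implemented: `mean_per_pair` (default) averages per-pair F1 over the pairs
in which the phoneme occurs; `pooled` sums counts first. A phoneme never
observed in a session is absent from the output rather than scored 0.

## Information transfer

For a feature-collapsed confusion matrix with n total counts, transmitted
information is computed as IT = Hx + Hy − Hxy with plug-in entropies in
nats over row margins, column margins and cells (0·log 0 = 0). This is
the Miller–Nicely covariance-of-categories measure; the common
computational shorthand IT = log n + hx + hy − hxy with
h = −(1/n) Σ s log s is the same quantity. IT is 0 for independent
(rank-1) matrices and log k for a k-subtype identity channel — both limits
are tested to 1e-9.

Relative IT divides by the stimulus subtype entropy Hstim (which equals
Hx of the same matrix), giving a base-invariant fraction reported as a
percentage. When the presented stimuli span a single subtype, Hstim = 0
and the feature's relative IT is reported as *undefined* (NaN / hatched
bar) — not 0% and not 100% — because a constant feature transmits no
distinguishing information and any number would overstate what was
measured. Relatedly, phoneme confusions confined within one subtype (IY↔IH
for vowel place) leave that feature at 100% by design; near-perfect
feature scores must be read alongside the per-phoneme F1 grids.

Routing conventions for the confusion matrices: deletions go to the
stimulus phoneme's *unclassified* column; cross-class substitutions
(rare, given the ≥5 penalty) are routed to the unclassified column of the
stimulus phoneme's matrix by default (`cross_class="drop"` discards them
instead); insertions contribute nothing because no stimulus phoneme was
presented. The unclassified column is kept as its own response category
during feature collapse so that missed phonemes depress transfer
(`keep_unclassified=False` reverts to classified-only analysis).

Per-phoneme response entropy (the validation statistic) is explicitly in
bits: for each presented phoneme, the Shannon entropy of its row
distribution over same-class response phonemes plus unclassified.

## Synthetic data

The generator emulates a speech-test session: sentences of 3–8 words
drawn uniformly from the lexicon, and responses derived per phoneme —
deletion with probability `p_del`, else substitution with probability
`p_sub` (the replacement drawn from the phoneme's similar tier with
probability `p_sub_similar`, else uniformly within its class), plus an
insertion at each inter-phoneme gap with probability `p_ins`, drawn from
the class of the nearest (preceding) stimulus phoneme. Defaults
(p_sub 0.10, p_sub_similar 0.5, p_del 0.05, p_ins 0.02) represent a
mildly impaired listener and are the regime used for the validation
contrast. All randomness flows through a seeded `numpy` generator.

What this does *not* model: top-down contextual repair (real listeners
guess words from sentence context, which inflates sentence-test accuracy),
word-substitution errors, attention lapses, and acoustic confusability
beyond the feature tiers. Passing validation on synthetic data shows the
pipeline's statistics behave correctly and directionally as they do on
real data (actual ≫ deranged); it does not calibrate absolute values for
any clinical population.

Derangements are drawn by rejection from uniform permutations (expected
≈ e attempts), giving the uniform distribution over derangements; the
n = 4 case is chi-square-tested against its nine derangements.

## Problem sizes

The test suite exercises the brute-force oracle on all sequence pairs of
length ≤ 2 over a seven-phoneme alphabet plus 4,000 seeded random pairs of
length ≤ 4 (~7,000 pairs, exact agreement required), and the validation
contrast on a 200-pair corpus; both complete in seconds. Longer sentences
(tens of phonemes) align in milliseconds per pair under the O(m·n)
three-state DP.

## Known limitations

- The feature table's coarse pairs (TH/V etc.) mean some substitution
  tiers group phonemes a finer featureisation would separate.
- Small sessions overestimate transmitted information (the plug-in IT
  estimator is biased upward); no bias correction or bootstrap interval
  is implemented — accumulate responses before reading phonemegrams
  quantitatively.
- First-pronunciation transcription can mis-transcribe heteronyms
  ("live", "read"); use overrides where the intended reading is known.
- Alignment quality degrades for very sparse or random responses, where
  several alignments may tie and the canonical pick is a convention.
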