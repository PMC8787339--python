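"""Score a synthetic listening session: F1 table and phonemegram.

Simulates a 50-sentence session for a listener with mild, structured
errors (10% substitutions biased to similar phonemes, 5% deletions, 2%
insertions), aligns every pair, and reports per-phoneme F1 scores plus
the relative information transfer of the ten phonological features.
"""

from phonalign import (CorruptionSpec, align_pairs, build_confusion,
                       make_corpus, phonemegram, score_table, tally)

pairs = make_corpus(50, CorruptionSpec(seed=7))
alignments = align_pairs(pairs)

table = score_table([tally(a) for a in alignments])
print("Per-phoneme F1 (percent), worst ten:")
print(table.sort_values("F1_percent").head(10).to_string(index=False))

cons, vows = build_confusion(alignments)
pg = phonemegram(cons, vows)
print("\nPhonemegram (relative information transfer, percent):")
print(pg[["feature", "band", "relative_percent"]].to_string(index=False))
print("\nValues near 100 mean the feature survives transmission even when")
print("individual phonemes are confused within a feature subtype.")
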