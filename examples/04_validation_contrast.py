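"""Actual vs deranged responses: the program's robustness check.

Responses carry information about their own stimuli. Re-pairing the same
responses with the wrong stimuli (a derangement: no response keeps its own
stimulus) should therefore depress every statistic the pipeline computes.
This script runs both conditions on a 200-pair synthetic corpus.
"""

import numpy as np

from phonalign import CorruptionSpec, make_corpus, validation_report

pairs = make_corpus(200, CorruptionSpec(seed=11))
report = validation_report(pairs, seed=11)

print("Mean correct phonemes per pair:")
print(f"  actual:   {np.mean(report.correct_counts_actual):.2f}")
print(f"  deranged: {np.mean(report.correct_counts_deranged):.2f}")

ent = report.entropy_frame().dropna()
frac = (ent["actual_bits"] < ent["deranged_bits"]).mean()
diff = (ent["deranged_bits"] - ent["actual_bits"]).mean()
print(f"\nPhonemes with lower response entropy in the actual condition: "
      f"{100 * frac:.0f}%")
print(f"Mean entropy excess of the deranged condition: {diff:.2f} bits")

pa = report.phonemegram_actual.set_index("feature")["relative_percent"]
pd_ = report.phonemegram_deranged.set_index("feature")["relative_percent"]
print("\nRelative information transfer (percent):")
for feature in pa.index:
    print(f"  {feature:<13} actual {pa[feature]:6.1f}   "
          f"deranged {pd_[feature]:6.1f}")
print("\nEvery feature transmits more information in the actual pairing —")
print("the pipeline distinguishes real listening data from shuffled data.")
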