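"""Transcribe one stimulus-response pair and align it.

The stimulus word "fun" (F AH N) was heard as "thin" (TH IH N). The
aligner pairs the two phoneme strings under feature-tiered costs; the
minimum edit distance (MED) of 2.2 decomposes into a fricative-fricative
substitution TH<-F charged 1.3, a vowel-vowel substitution IH<-AH charged
0.9, and a free match on N.
"""

from phonalign import align, render_alignment, transcribe

stimulus = transcribe("fun")
response = transcribe("thin")
print(f"stimulus: {stimulus.spaced()}")
print(f"response: {response.spaced()}")
print()
alignment = align(stimulus, response)
print(render_alignment(alignment))
print()
print("Rows: stimulus, response, operations (M match, S substitution,")
print("D deletion, I insertion). The F1 list scores each phoneme:")
print("N was transmitted (100%), F and AH were not (0%).")
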