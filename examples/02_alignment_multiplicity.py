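"""Why history-dependent, similarity-tiered costs: alignment uniqueness.

A sentence pair with little overlap ("These are your books" heard as
"We live on the earth") has many equally cheap alignments under the
legacy simple costs (indel 1, substitution 2, match 0), so the reported
alignment is arbitrary. The feature-tiered costs with switch penalties
single out one optimum.
"""

from phonalign import enumerate_optimal, make_simple_cost_model, transcribe

stimulus = transcribe("These are your books")
response = transcribe("We live on the earth")
print(f"stimulus: {stimulus.spaced()}")
print(f"response: {response.spaced()}")

default_alignments, _ = enumerate_optimal(stimulus, response)
print(f"\nfeature-tiered costs: {len(default_alignments)} "
      "co-optimal alignment(s)")

simple_alignments, exhausted = enumerate_optimal(
    stimulus, response, model=make_simple_cost_model(), cap=1000)
more = ">" if exhausted else ""
print(f"legacy simple costs:  {more}{len(simple_alignments)} "
      "co-optimal alignment(s)")
print("\nA unique optimum means the downstream confusion counts are")
print("well-defined rather than an arbitrary pick among ties.")
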