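# Default edit-operation costs for phoneme alignment.
#
# Every cost depends on the previous edit operation, which discourages
# switching between gap runs and substitution runs. "Substitution" rows
# are tiered by the phonological similarity of the stimulus/response pair;
# "match" is the zero-tier of substitution. At the start of a sequence
# (no previous operation) the no-switch column applies: insertion 1.0,
# deletion 1.0, substitution = its prev-substitution value.
insertion:
  prev_ins: 1.0
  prev_sub: 1.5
  prev_del: 1.5
deletion:
  prev_del: 1.0
  prev_ins: 1.5
  prev_sub: 1.5
substitution:           # [prev_sub, prev_ins, prev_del]
  vowel_consonant:      [5.0, 5.1, 5.5]
  consonant_consonant:  [1.75, 1.85, 2.25]
  same_manner_consonant: [1.3, 1.4, 1.8]
  similar_consonant:    [1.2, 1.3, 1.7]
  vowel_vowel:          [0.9, 0.8, 1.4]
  similar_vowel:        [0.65, 0.75, 1.15]
  match:                [0.0, 0.1, 0.2]
# Consonant pairs granted the "similar consonant" tier: voicing cognates.
similar_consonant_pairs:
  - [P, B]
  - [T, D]
  - [K, G]
  - [F, V]
  - [S, Z]
  - [SH, ZH]
  - [CH, JH]
  - [TH, DH]
# Two vowels are "similar" when at most this many of their four features differ.
similar_vowel_max_differences: 1
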