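# phonalign

Phoneme-level analysis of speech-perception tests.

Audiologists and speech pathologists score speech tests (word and sentence
lists presented to people using hearing aids or cochlear implants) at the
word or sentence level; the phoneme-level error structure — which sounds a
listener confuses, misses, or hallucinates — is usually left on the table.
`phonalign` automates that analysis for stimulus–response pairs of written
text:

1. **Transcription.** Each stimulus and response is converted to a string
   of stress-free ARPAbet phonemes (15 vowels, 24 consonants) via a
   CMUDict-format pronouncing lexicon, with a user override lexicon for
   nonsense responses (a listener reporting "kints" for "pinch" gets a
   hand-entered `KINTS K IH N T S`).
2. **Alignment.** The two phoneme strings are aligned by a modified
   Levenshtein minimum edit distance (MED) computed by dynamic programming.
   Costs depend on the *previous* edit operation (switching between gap
   runs and substitution runs is penalised, as in affine-gap alignment)
   and, for substitutions, on the phonological similarity of the pair:
   matches < similar vowels < vowels < similar (cognate) consonants <
   same-manner consonants < consonants < vowel–consonant. All co-optimal
   alignments can be enumerated; the tiered costs make the optimum unique
   in virtually all cases.
3. **Scoring.** Per phoneme *p*, aligned columns yield true positives
   (matches), false negatives (deletions, substituted stimuli) and false
   positives (insertions, substituted responses), and the F1 score
   (Sørensen–Dice coefficient)

   F1(p) = 2·TP / (2·TP + FP + FN),

   averaged over pairs and displayed on the classic place × manner/height
   grids for vowels, voiced and unvoiced consonants.
4. **Phonemegram.** Stimulus×response confusion matrices (24×25 consonants,
   15×16 vowels, the extra column for unclassified/empty responses) are
   collapsed over each of ten phonological features, and the transmitted
   information computed after Miller & Nicely:

   IT = Hx + Hy − Hxy  (equivalently log n + hx + hy − hxy with
   h = −(1/n) Σ s·log s over margins/cells),

   normalised by the stimulus feature entropy Hstim to a *relative*
   information transfer in [0, 100]%. The ten bars, ordered and coloured by
   the acoustic frequency band each feature chiefly occupies, form the
   phonemegram.
5. **Validation.** A set of pairs is contrasted with its *derangement*
   (responses permuted so none keeps its own stimulus): correct-phoneme
   histograms, per-phoneme response entropies (bits), and feature
   information transfer separate real from shuffled data.

Because clinical response corpora are not redistributable, the package
includes a synthetic-data module that generates sentence stimuli from the
bundled lexicon and corrupts them with parameterised substitution /
deletion / insertion rates.

## Worked example

```python
>>> from phonalign import align, render_alignment, transcribe
>>> stimulus, response = transcribe("fun"), transcribe("thin")
>>> print(render_alignment(align(stimulus, response)))
F  AH N
TH IH N
S  S  M
MED: 2.2
F1: AH: 0%, F: 0%, IH: 0%, N: 100%, TH: 0%
```

The MED of 2.2 decomposes into a same-manner fricative substitution
TH←F (1.3), a vowel–vowel substitution IH←AH after a substitution (0.9),
and a free match on N; only N counts as a transmitted phoneme.

The `examples/` directory holds narrative scripts, one per capability
(single-pair alignment, alignment-uniqueness contrast, session F1 +
phonemegram, actual-vs-deranged validation). A thin CLI wraps the same
functions:

```bash
phonalign transcribe "these are your books"
phonalign align pairs.tsv --overrides my_overrides.txt
phonalign analyze pairs.tsv --out results/
phonalign simulate --n-pairs 200 --out synthetic.tsv
phonalign validate synthetic.tsv --phonemic
```

Pair files are TSV (`id  stimulus  response`), orthographic by default or
phonemic with `--phonemic`. The cost model and feature table are editable
data files (`--costs my_costs.yaml`; `src/phonalign/data/`).

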