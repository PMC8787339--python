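"""Synthetic stimulus-response pairs and the actual-vs-random validation design.

Real speech-test response corpora are not redistributable, so this module
fabricates them: sentences are sampled from the bundled lexicon, and
responses are derived from stimuli by seeded phoneme-level corruption —
independent deletions and substitutions per stimulus phoneme (substitutions
biased towards phonologically similar neighbours, the dominant error mode
in hearing-loss data) plus per-gap insertions. This emulates a listener
with imperfect but structured perception; it does not model top-down
contextual repair, word-level guessing, or attention lapses.

The validation design contrasts a set of actual pairs with the same
responses *deranged* — randomly permuted so no response stays with its own
stimulus — and compares three quantities: the per-pair correct-phoneme
histogram, the per-phoneme response entropy, and the relative information
transfer of the ten phonological features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .align import Alignment, align
from .costs import CostModel, classify_substitution, default_cost_model
from .features import FeatureTable, default_feature_table
from .lexicon import Lexicon, bundled_lexicon
from .phonemes import CONSONANTS, VOWELS, PhonemeSequence, is_vowel
from .scoring import correct_phoneme_count
from .infotransfer import build_confusion, phonemegram, response_entropy


@dataclass(frozen=True)
class CorruptionSpec:
    """Error rates for synthesising a response from a stimulus.

    Per stimulus phoneme, deletion with probability ``p_del``, else
    substitution with probability ``p_sub`` (mutually exclusive; their sum
    must not exceed 1). A substitution draws a same-class replacement, from
    the phoneme's similar tier with probability ``p_sub_similar`` (voicing
    cognates / same-manner consonants; near-identical vowels), otherwise
    uniformly from the rest of the class. Each of the len+1 gaps receives
    an insertion with probability ``p_ins``, drawn uniformly from the class
    of the nearest stimulus phoneme.

    The defaults are the mild-corruption regime used for validation.
    """

    p_sub: float = 0.10
    p_sub_similar: float = 0.5
    p_del: float = 0.05
    p_ins: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_sub", "p_sub_similar", "p_del", "p_ins"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.p_sub + self.p_del > 1.0:
            raise ValueError("p_sub + p_del must not exceed 1")


def _similar_candidates(
    phoneme: str,
    features: FeatureTable,
    model: CostModel,
) -> list[str]:
    """Same-tier confusion candidates for a phoneme (never the phoneme itself)."""
    if is_vowel(phoneme):
        pool = [
            v for v in VOWELS
            if v != phoneme
            and classify_substitution(phoneme, v, features, model)
            == "similar_vowel"
        ]
    else:
        pool = [
            c for c in CONSONANTS
            if c != phoneme
            and classify_substitution(phoneme, c, features, model)
            in ("similar_consonant", "same_manner_consonant")
        ]
    return pool


def corrupt(
    stimulus: PhonemeSequence | Sequence[str],
    spec: CorruptionSpec,
    rng: np.random.Generator | None = None,
    features: FeatureTable | None = None,
    model: CostModel | None = None,
) -> PhonemeSequence:
    """Derive a noisy response from a stimulus under a corruption spec.

    Reproducible: with no explicit ``rng``, a fresh generator is seeded
    from ``spec.seed``.
    """
    features = features or default_feature_table()
    model = model or default_cost_model()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    phonemes = (stimulus.phonemes if isinstance(stimulus, PhonemeSequence)
                else tuple(stimulus))

    def maybe_insert(anchor: str | None) -> list[str]:
        if anchor is not None and rng.random() < spec.p_ins:
            pool = VOWELS if is_vowel(anchor) else CONSONANTS
            return [pool[rng.integers(len(pool))]]
        return []

    out: list[str] = []
    out.extend(maybe_insert(phonemes[0] if phonemes else None))
    for p in phonemes:
        u = rng.random()
        if u < spec.p_del:
            pass  # deleted
        elif u < spec.p_del + spec.p_sub:
            similar = _similar_candidates(p, features, model)
            if similar and rng.random() < spec.p_sub_similar:
                out.append(similar[rng.integers(len(similar))])
            else:
                pool = [q for q in (VOWELS if is_vowel(p) else CONSONANTS)
                        if q != p]
                out.append(pool[rng.integers(len(pool))])
        else:
            out.append(p)
        out.extend(maybe_insert(p))
    return PhonemeSequence(tuple(out))


def derange(
    responses: Sequence,
    seed: int | np.random.Generator = 0,
) -> list:
    """Randomly permute responses so none stays with its own stimulus.

    Rejection-samples uniform permutations until one is a derangement
    (about e tries in expectation), so all derangements are equally
    likely. Requires at least two responses.
    """
    n = len(responses)
    if n < 2:
        raise ValueError("a derangement requires at least two responses")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return [responses[i] for i in perm]


def make_sentences(
    n: int,
    lexicon: Lexicon | None = None,
    seed: int | np.random.Generator = 0,
    words_per_sentence: tuple[int, int] = (3, 8),
) -> list[PhonemeSequence]:
    """Sample n sentence stimuli from a lexicon (first pronunciations).

    Word count is uniform over ``words_per_sentence`` inclusive; words are
    drawn uniformly with replacement from the lexicon vocabulary.
    """
    lexicon = lexicon if lexicon is not None else bundled_lexicon()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    vocab = sorted(lexicon.words())
    lo, hi = words_per_sentence
    out = []
    for _ in range(n):
        k = int(rng.integers(lo, hi + 1))
        phonemes: list[str] = []
        bounds: list[int] = []
        for _ in range(k):
            word = vocab[rng.integers(len(vocab))]
            bounds.append(len(phonemes))
            phonemes.extend(lexicon.first(word))
        out.append(PhonemeSequence(tuple(phonemes), tuple(bounds)))
    return out


def make_corpus(
    n_pairs: int,
    spec: CorruptionSpec | None = None,
    lexicon: Lexicon | None = None,
    seed: int | None = None,
) -> list[tuple[PhonemeSequence, PhonemeSequence]]:
    """A synthetic session: n (stimulus, response) pairs under one spec."""
    spec = spec or CorruptionSpec()
    master = np.random.default_rng(spec.seed if seed is None else seed)
    stimuli = make_sentences(n_pairs, lexicon, master)
    return [(s, corrupt(s, spec, master)) for s in stimuli]


@dataclass
class ValidationReport:
    """Actual-vs-deranged comparison: the three validation computations."""

    correct_counts_actual: list[int]
    correct_counts_deranged: list[int]
    entropy_actual: dict[str, float] = field(default_factory=dict)
    entropy_deranged: dict[str, float] = field(default_factory=dict)
    phonemegram_actual: pd.DataFrame | None = None
    phonemegram_deranged: pd.DataFrame | None = None

    def entropy_frame(self) -> pd.DataFrame:
        """Per-phoneme response entropies (bits), both conditions."""
        phonemes = sorted(set(self.entropy_actual) | set(self.entropy_deranged))
        return pd.DataFrame({
            "phoneme": phonemes,
            "actual_bits": [self.entropy_actual.get(p) for p in phonemes],
            "deranged_bits": [self.entropy_deranged.get(p) for p in phonemes],
        })

    def histogram_frame(self) -> pd.DataFrame:
        """Frequency of per-pair correct-phoneme counts, both conditions."""
        top = max(self.correct_counts_actual + self.correct_counts_deranged,
                  default=0)
        bins = range(top + 1)
        actual = np.bincount(self.correct_counts_actual, minlength=top + 1)
        deranged = np.bincount(self.correct_counts_deranged, minlength=top + 1)
        return pd.DataFrame({"correct_phonemes": list(bins),
                             "actual_pairs": actual,
                             "deranged_pairs": deranged})


def _analyze(alignments: list[Alignment], features: FeatureTable):
    cons, vows = build_confusion(alignments)
    return (
        [correct_phoneme_count(a) for a in alignments],
        response_entropy(cons, vows),
        phonemegram(cons, vows, features),
    )


def validation_report(
    pairs: Sequence[tuple[PhonemeSequence, PhonemeSequence]],
    seed: int = 0,
    features: FeatureTable | None = None,
    model: CostModel | None = None,
) -> ValidationReport:
    """Run the full pipeline on actual pairs and on their derangement.

    The deranged condition reuses the same responses, permuted so that no
    response faces its own stimulus; differences between the two runs are
    therefore attributable purely to stimulus-response correspondence.
    """
    features = features or default_feature_table()
    model = model or default_cost_model()
    stimuli = [s for s, _ in pairs]
    responses = [r for _, r in pairs]
    shuffled = derange(responses, seed)
    actual = [align(s, r, features, model) for s, r in zip(stimuli, responses)]
    deranged = [align(s, r, features, model) for s, r in zip(stimuli, shuffled)]
    counts_a, ent_a, pg_a = _analyze(actual, features)
    counts_d, ent_d, pg_d = _analyze(deranged, features)
    return ValidationReport(
        correct_counts_actual=counts_a,
        correct_counts_deranged=counts_d,
        entropy_actual=ent_a,
        entropy_deranged=ent_d,
        phonemegram_actual=pg_a,
        phonemegram_deranged=pg_d,
    )


def write_pairs_tsv(path, pairs, ids=None) -> None:
    """Write pairs as phoneme-level TSV: id, stimulus, response (ARPAbet)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["id", "stimulus_phonemes", "response_phonemes"])
        for i, (s, r) in enumerate(pairs):
            pid = ids[i] if ids is not None else i + 1
            writer.writerow([pid, s.spaced(), r.spaced()])


def read_pairs_tsv(path) -> list[tuple[str, PhonemeSequence, PhonemeSequence]]:
    """Read phoneme-level TSV pairs written by :func:`write_pairs_tsv`."""
    import csv

    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append((
                row["id"],
                PhonemeSequence.from_spaced(row["stimulus_phonemes"]),
                PhonemeSequence.from_spaced(row["response_phonemes"]),
            ))
    return out
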