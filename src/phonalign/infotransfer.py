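"""Confusion matrices, information transfer, and the phonemegram.

From a set of alignments, two stimulus-by-response confusion matrices are
accumulated (24x25 consonants, 15x16 vowels; one extra response column for
*unclassified* phonemes, i.e. stimulus phonemes with no same-class response
— deletions and, by default, cross-class substitutions). Each matrix can
then be collapsed over one phonological feature, merging phonemes that
share a subtype, and the transmitted information through the resulting
channel computed following Miller and Nicely's covariance-of-categories
analysis:

    IT = log(n) + hx + hy - hxy,   h = -(1/n) * sum s log(s)

with the sums over non-zero row totals, column totals, and cells
respectively (0·log 0 := 0). Equivalently, IT = Hx + Hy - Hxy in terms of
the usual plug-in entropies, which is what the :class:`ITResult` fields
store. The *relative* information transfer normalises IT by the stimulus
entropy Hstim of the feature's subtype distribution; it is the fraction of
presented feature information that survived to the response, and is
invariant to the logarithm base. Natural logs are used internally; the
per-phoneme response entropies of :func:`response_entropy` are explicitly
base 2 (bits).

The *phonemegram* is the vector of relative IT percentages for all ten
features, annotated with the acoustic frequency band each feature chiefly
occupies (low: nasality, vowel height, manner, voicing; mid, vowels:
contour, vowel place, vowel length; mid, consonants: affrication; high:
sibilance, consonant place). A feature whose presented stimuli span a
single subtype has Hstim = 0 and its relative IT is reported as undefined
(None) rather than 0 or 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .align import Alignment
from .costs import OP_DEL, OP_MATCH, OP_SUB
from .features import ALL_FEATURES, FeatureTable, default_feature_table
from .phonemes import CONSONANTS, VOWELS, is_vowel

UNCLASSIFIED = "unclassified"

#: Acoustic frequency band for each feature (phonemegram bar colouring).
FEATURE_BANDS: dict[str, str] = {
    "nasality": "low",
    "vowel_height": "low",
    "manner": "low",
    "voicing": "low",
    "contour": "mid_vowel",
    "vowel_place": "mid_vowel",
    "vowel_length": "mid_vowel",
    "affrication": "mid_consonant",
    "sibilance": "high",
    "place": "high",
}


@dataclass
class ConfusionMatrix:
    """Stimulus x (response + unclassified) counts for one phoneme class."""

    klass: str
    counts: np.ndarray  # shape (N, N+1), int

    @property
    def phonemes(self) -> tuple[str, ...]:
        return VOWELS if self.klass == "vowel" else CONSONANTS

    @property
    def response_labels(self) -> tuple[str, ...]:
        return self.phonemes + (UNCLASSIFIED,)

    @classmethod
    def empty(cls, klass: str) -> "ConfusionMatrix":
        n = len(VOWELS) if klass == "vowel" else len(CONSONANTS)
        return cls(klass, np.zeros((n, n + 1), dtype=int))

    def increment(self, stimulus: str, response: str | None) -> None:
        """Count one stimulus phoneme; response None means unclassified."""
        i = self.phonemes.index(stimulus)
        j = self.counts.shape[1] - 1 if response is None \
            else self.phonemes.index(response)
        self.counts[i, j] += 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.phonemes),
                            columns=list(self.response_labels))


@dataclass
class FeatureMatrix:
    """A confusion matrix collapsed over one phonological feature."""

    feature: str
    row_subtypes: list[int]
    col_labels: list[object]  # subtype codes, possibly + "unclassified"
    counts: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_subtypes,
                            columns=self.col_labels)


@dataclass(frozen=True)
class ITResult:
    """Information-transfer summary for one feature matrix.

    Entropies are plug-in estimates in nats: ``hx``/``hy`` over the
    stimulus/response margins, ``hxy`` over the joint cells, so that
    ``it = hx + hy - hxy``. ``hstim`` is the stimulus-subtype entropy used
    for normalisation; ``relative`` is IT/Hstim in [0, 1], or None when
    Hstim = 0 (a single presented subtype transmits no information).
    """

    feature: str
    n: int
    hx: float
    hy: float
    hxy: float
    it: float
    hstim: float
    relative: float | None

    @property
    def relative_percent(self) -> float | None:
        return None if self.relative is None else 100.0 * self.relative


def build_confusion(
    alignments: Iterable[Alignment],
    cross_class: str = "unclassified",
) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    """Accumulate (consonant, vowel) confusion matrices from alignments.

    Matches and within-class substitutions count (stimulus, response);
    deletions count (stimulus, unclassified). Cross-class substitutions go
    to the stimulus phoneme's unclassified column when ``cross_class`` is
    ``"unclassified"`` (default) or are ignored when it is ``"drop"``.
    Insertions contribute nothing — there is no stimulus row to count.
    """
    if cross_class not in ("unclassified", "drop"):
        raise ValueError(f"unknown cross_class policy: {cross_class!r}")
    cons = ConfusionMatrix.empty("consonant")
    vows = ConfusionMatrix.empty("vowel")
    for alignment in alignments:
        for col in alignment.columns:
            if col.op == OP_DEL:
                matrix = vows if is_vowel(col.stimulus) else cons
                matrix.increment(col.stimulus, None)
            elif col.op in (OP_MATCH, OP_SUB):
                s_vowel = is_vowel(col.stimulus)
                matrix = vows if s_vowel else cons
                if s_vowel == is_vowel(col.response):
                    matrix.increment(col.stimulus, col.response)
                elif cross_class == "unclassified":
                    matrix.increment(col.stimulus, None)
    return cons, vows


def collapse_feature(
    matrix: ConfusionMatrix,
    feature: str,
    features: FeatureTable | None = None,
    keep_unclassified: bool = True,
) -> FeatureMatrix:
    """Collapse a phoneme confusion matrix over one feature's subtypes.

    Rows and response columns are grouped by the feature's subtype value;
    the unclassified column stays as its own response category (so missed
    phonemes depress transfer) unless ``keep_unclassified`` is False.
    """
    features = features or default_feature_table()
    if features.klass_of_feature(feature) != matrix.klass:
        raise ValueError(
            f"feature {feature!r} does not apply to {matrix.klass} phonemes")
    subtypes = features.subtypes(feature)
    index = {v: k for k, v in enumerate(subtypes)}
    ncols = len(subtypes) + (1 if keep_unclassified else 0)
    counts = np.zeros((len(subtypes), ncols), dtype=int)
    phonemes = matrix.phonemes
    for i, stim in enumerate(phonemes):
        row = index[features.value(stim, feature)]
        for j, resp in enumerate(phonemes):
            counts[row, index[features.value(resp, feature)]] += \
                matrix.counts[i, j]
        if keep_unclassified:
            counts[row, -1] += matrix.counts[i, -1]
    col_labels: list[object] = list(subtypes)
    if keep_unclassified:
        col_labels.append(UNCLASSIFIED)
    return FeatureMatrix(feature, subtypes, col_labels, counts)


def _neg_sum_slogs(values: np.ndarray, n: int) -> float:
    """-(1/n) * sum s log s over non-zero counts (0 log 0 := 0)."""
    s = values[values > 0].astype(float)
    return -float(np.sum(s * np.log(s))) / n


def information_transfer(fm: FeatureMatrix) -> ITResult:
    """Miller–Nicely transmitted information for one feature matrix."""
    n = fm.n
    if n == 0:
        raise ValueError("information transfer is undefined for n = 0")
    counts = fm.counts
    logn = math.log(n)
    # plug-in entropies in nats: H = log n - (1/n) sum s log s
    hx = logn + _neg_sum_slogs(counts.sum(axis=1), n)
    hy = logn + _neg_sum_slogs(counts.sum(axis=0), n)
    hxy = logn + _neg_sum_slogs(counts.ravel(), n)
    it = hx + hy - hxy
    # stimulus-subtype entropy from the row margins
    hstim = stimulus_entropy(counts.sum(axis=1))
    if hstim > 0:
        relative = min(max(it / hstim, 0.0), 1.0)
    else:
        relative = None
    return ITResult(fm.feature, n, hx, hy, hxy, it, hstim, relative)


def stimulus_entropy(subtype_counts: np.ndarray | list[int],
                     base: float = math.e) -> float:
    """Hstim = -sum (p_i/p_total) log(p_i/p_total) over presented subtypes."""
    counts = np.asarray(subtype_counts, dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log(p)) / math.log(base))


def phonemegram(
    cons: ConfusionMatrix,
    vows: ConfusionMatrix,
    features: FeatureTable | None = None,
    keep_unclassified: bool = True,
) -> pd.DataFrame:
    """Relative information transfer for all ten features, with bands.

    Returns a DataFrame ordered low -> high frequency band with columns
    feature, band, n, Hx, Hy, Hxy, IT, Hstim, relative_percent (NaN for
    features whose stimuli spanned a single subtype).
    """
    features = features or default_feature_table()
    rows = []
    for feature in ALL_FEATURES:
        matrix = vows if features.klass_of_feature(feature) == "vowel" else cons
        fm = collapse_feature(matrix, feature, features, keep_unclassified)
        if fm.n == 0:
            rows.append({"feature": feature, "band": FEATURE_BANDS[feature],
                         "n": 0, "Hx": np.nan, "Hy": np.nan, "Hxy": np.nan,
                         "IT": np.nan, "Hstim": 0.0,
                         "relative_percent": np.nan})
            continue
        res = information_transfer(fm)
        rows.append({
            "feature": feature,
            "band": FEATURE_BANDS[feature],
            "n": res.n,
            "Hx": res.hx,
            "Hy": res.hy,
            "Hxy": res.hxy,
            "IT": res.it,
            "Hstim": res.hstim,
            "relative_percent": (np.nan if res.relative_percent is None
                                 else res.relative_percent),
        })
    return pd.DataFrame(rows)


def response_entropy(
    cons: ConfusionMatrix,
    vows: ConfusionMatrix,
) -> dict[str, float]:
    """Per-stimulus-phoneme response entropy in bits.

    For each presented phoneme, the Shannon entropy of its row distribution
    over response categories (same-class phonemes + unclassified). Phonemes
    never presented are omitted.
    """
    out: dict[str, float] = {}
    for matrix in (cons, vows):
        for i, p in enumerate(matrix.phonemes):
            row = matrix.counts[i].astype(float)
            total = row.sum()
            if total == 0:
                continue
            probs = row[row > 0] / total
            out[p] = float(-np.sum(probs * np.log2(probs)))
    return out
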