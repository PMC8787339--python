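"""Phonological feature table for the 39-phoneme ARPAbet inventory.

Each vowel carries four features (height, contour, place, length) and each
consonant six (nasality, manner, voicing, affrication, sibilance, place),
with small-integer subtype codes:

==============  =========================================================
feature         subtype codes
==============  =========================================================
vowel_height    0 = low, 1 = mid, 2 = high
contour         0 = rising, 1 = flat, 2 = falling
vowel_place     0 = front, 1 = central, 2 = back
vowel_length    0 = short, 1 = long
nasality        0 = oral, 1 = nasal
manner          0 = stop, 1 = nasal, 2 = fricative, 3 = glide, 4 = affricate
voicing         0 = unvoiced, 1 = voiced
affrication     0 = none, 1 = frication noise present
sibilance       0 = non-sibilant, 1 = sibilant
place           0 = front, 1 = center, 2 = back
==============  =========================================================

The default table ships as an editable CSV (``data/phoneme_features.csv``);
alternative tables can be loaded by path. Note that the default table
contains some feature-identical phoneme pairs (TH/V, DH/F, SH/S, ZH/Z):
the feature space is coarser than the phoneme inventory.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .phonemes import CONSONANTS, VOWELS, InvalidPhonemeError, is_vowel

VOWEL_FEATURES: tuple[str, ...] = (
    "vowel_height", "contour", "vowel_place", "vowel_length",
)
CONSONANT_FEATURES: tuple[str, ...] = (
    "nasality", "manner", "voicing", "affrication", "sibilance", "place",
)
#: All ten features, ordered low -> high acoustic frequency band
#: (the phonemegram display order).
ALL_FEATURES: tuple[str, ...] = (
    "nasality", "vowel_height", "manner", "voicing",
    "contour", "vowel_place", "vowel_length",
    "affrication", "sibilance", "place",
)


class FeatureTable:
    """Per-phoneme phonological feature vectors, split by phoneme class."""

    def __init__(self, frame: pd.DataFrame):
        frame = frame.set_index("phoneme") if "phoneme" in frame.columns else frame
        vowels = frame.loc[list(VOWELS), list(VOWEL_FEATURES)].astype(int)
        consonants = frame.loc[list(CONSONANTS), list(CONSONANT_FEATURES)].astype(int)
        self.vowels = vowels
        self.consonants = consonants
        self._lookup: dict[str, dict[str, int]] = {}
        for p in VOWELS:
            self._lookup[p] = vowels.loc[p].to_dict()
        for p in CONSONANTS:
            self._lookup[p] = consonants.loc[p].to_dict()

    @classmethod
    def load(cls, path: str | Path | None = None) -> "FeatureTable":
        """Load a feature table CSV; the bundled default when path is None."""
        if path is None:
            ref = resources.files("phonalign.data") / "phoneme_features.csv"
            with resources.as_file(ref) as p:
                frame = pd.read_csv(p)
        else:
            frame = pd.read_csv(path)
        return cls(frame)

    def klass_of_feature(self, feature: str) -> str:
        if feature in VOWEL_FEATURES:
            return "vowel"
        if feature in CONSONANT_FEATURES:
            return "consonant"
        raise KeyError(f"unknown feature: {feature!r}")

    def value(self, phoneme: str, feature: str) -> int:
        try:
            row = self._lookup[phoneme]
        except KeyError:
            raise InvalidPhonemeError(f"unknown phoneme: {phoneme!r}") from None
        return row[feature]

    def vector(self, phoneme: str) -> dict[str, int]:
        """The feature->subtype mapping for one phoneme (4 or 6 entries)."""
        try:
            return dict(self._lookup[phoneme])
        except KeyError:
            raise InvalidPhonemeError(f"unknown phoneme: {phoneme!r}") from None

    def n_feature_differences(self, a: str, b: str) -> int:
        """Count differing features between two same-class phonemes."""
        if is_vowel(a) != is_vowel(b):
            raise ValueError("phonemes are not of the same class")
        va, vb = self._lookup[a], self._lookup[b]
        return sum(va[f] != vb[f] for f in va)

    def subtypes(self, feature: str) -> list[int]:
        """Sorted distinct subtype codes a feature takes in the table."""
        table = self.vowels if feature in VOWEL_FEATURES else self.consonants
        return sorted(table[feature].unique().tolist())


_default: FeatureTable | None = None


def default_feature_table() -> FeatureTable:
    """The bundled feature table (cached)."""
    global _default
    if _default is None:
        _default = FeatureTable.load()
    return _default
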