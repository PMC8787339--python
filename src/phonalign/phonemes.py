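"""ARPAbet phoneme inventory and phoneme sequences.

The stress-free ARPAbet inventory used throughout the package: 39 phonemes,
15 vowels and 24 consonants. Vowel and consonant tuples are kept in the
canonical feature-table order so confusion matrices have a fixed layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

VOWELS: tuple[str, ...] = (
    "AA", "AE", "AH", "AO", "AW", "AY", "EH", "ER",
    "EY", "IH", "IY", "OW", "OY", "UH", "UW",
)

CONSONANTS: tuple[str, ...] = (
    "B", "CH", "D", "DH", "F", "G", "HH", "JH", "K", "L", "M", "N",
    "NG", "P", "R", "S", "SH", "T", "TH", "V", "W", "Y", "Z", "ZH",
)

PHONEMES: tuple[str, ...] = VOWELS + CONSONANTS

_VOWEL_SET = frozenset(VOWELS)
_PHONEME_SET = frozenset(PHONEMES)


class InvalidPhonemeError(ValueError):
    """Raised when a symbol is not in the 39-phoneme stress-free inventory."""


def is_vowel(symbol: str) -> bool:
    return symbol in _VOWEL_SET


def is_phoneme(symbol: str) -> bool:
    return symbol in _PHONEME_SET


def klass(symbol: str) -> str:
    """Return ``"vowel"`` or ``"consonant"`` for a valid phoneme symbol."""
    if symbol in _VOWEL_SET:
        return "vowel"
    if symbol in _PHONEME_SET:
        return "consonant"
    raise InvalidPhonemeError(f"not an ARPAbet phoneme: {symbol!r}")


def validate(symbol: str) -> str:
    if symbol not in _PHONEME_SET:
        raise InvalidPhonemeError(f"not an ARPAbet phoneme: {symbol!r}")
    return symbol


@dataclass(frozen=True)
class PhonemeSequence:
    """An ordered string of phonemes with word-boundary bookkeeping.

    ``word_boundaries`` holds the index of the first phoneme of each word;
    it is display metadata only and plays no role in alignment. For a
    single-word (or word-structure-agnostic) sequence it is ``(0,)``.
    """

    phonemes: tuple[str, ...]
    word_boundaries: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        for p in self.phonemes:
            validate(p)
        if not self.word_boundaries:
            bounds = (0,) if self.phonemes else ()
            object.__setattr__(self, "word_boundaries", bounds)
        bounds = self.word_boundaries
        if self.phonemes:
            if bounds[0] != 0 or any(b >= len(self.phonemes) for b in bounds):
                raise ValueError("word boundaries out of range")
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                raise ValueError("word boundaries must be strictly increasing")
        elif bounds:
            raise ValueError("empty sequence cannot have word boundaries")

    @classmethod
    def from_symbols(cls, symbols: Sequence[str]) -> "PhonemeSequence":
        return cls(tuple(symbols))

    @classmethod
    def from_spaced(cls, text: str) -> "PhonemeSequence":
        """Parse a space-separated ARPAbet string, e.g. ``"F AH N"``."""
        return cls(tuple(text.split()))

    def __len__(self) -> int:
        return len(self.phonemes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.phonemes)

    def __getitem__(self, i: int) -> str:
        return self.phonemes[i]

    def spaced(self) -> str:
        return " ".join(self.phonemes)

    def words(self) -> list[tuple[str, ...]]:
        """Split the sequence back into per-word phoneme tuples."""
        out = []
        bounds = list(self.word_boundaries) + [len(self.phonemes)]
        for a, b in zip(bounds, bounds[1:]):
            out.append(self.phonemes[a:b])
        return out
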