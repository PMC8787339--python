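"""CMUDict-format lexicon parsing and orthography-to-phoneme transcription.

Reads pronouncing lexicons in the plain-text CMUDict 0.7b dialect:
comment lines start with ``;;;``, entry lines are ``WORD  P1 P2 ...`` with
alternate pronunciations suffixed ``WORD(2)``, ``WORD(3)``, ... Lexical
stress digits on vowels are stripped on load — they do not affect any
downstream analysis here.

Transcription resolves each word against an optional override lexicon
first, then the main lexicon, taking the first listed pronunciation.
Overrides are how out-of-vocabulary or nonsense responses are handled:
a listener who reports "kints" for "pinch" gets a hand-entered entry
``KINTS  K IH N T S`` rather than a failed run.
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path

from .phonemes import PhonemeSequence, is_phoneme

_ALT_RE = re.compile(r"^(?P<word>.+)\((?P<n>\d+)\)$")
_STRESS_RE = re.compile(r"^(?P<sym>[A-Z]+?)(?P<digit>[0-2])?$")
_EDGE_PUNCT = '.,;:!?"()-'


class LexiconParseError(ValueError):
    """Raised on a malformed lexicon line or invalid phoneme token."""


class UnresolvedWordError(KeyError):
    """Raised when a word is absent from both the lexicon and the overrides."""

    def __init__(self, word: str):
        super().__init__(word)
        self.word = word

    def __str__(self) -> str:
        return (f"word not found in lexicon or overrides: {self.word!r} "
                "(add an override entry to transcribe it)")


def strip_stress(token: str) -> str:
    """Strip a trailing lexical-stress digit and validate the symbol.

    ``"AH0" -> "AH"``, ``"IY1" -> "IY"``, ``"K" -> "K"``.
    """
    match = _STRESS_RE.match(token)
    if match:
        sym = match.group("sym")
        if is_phoneme(sym):
            return sym
    raise LexiconParseError(f"not an ARPAbet token: {token!r}")


class Lexicon:
    """word -> ordered list of stress-free pronunciations."""

    def __init__(self, entries: dict[str, list[tuple[str, ...]]] | None = None):
        self.entries: dict[str, list[tuple[str, ...]]] = entries or {}

    def __contains__(self, word: str) -> bool:
        return word.upper() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def add(self, word: str, pronunciation: tuple[str, ...] | list[str]) -> None:
        pron = tuple(pronunciation)
        if not pron:
            raise LexiconParseError(f"empty pronunciation for {word!r}")
        for p in pron:
            if not is_phoneme(p):
                raise LexiconParseError(
                    f"invalid phoneme {p!r} in pronunciation of {word!r}")
        self.entries.setdefault(word.upper(), []).append(pron)

    def pronunciations(self, word: str) -> list[tuple[str, ...]]:
        return self.entries[word.upper()]

    def first(self, word: str) -> tuple[str, ...]:
        """The first listed pronunciation (the transcription default)."""
        return self.entries[word.upper()][0]

    def words(self) -> list[str]:
        return list(self.entries)


def _parse_lines(lines, source: str) -> Lexicon:
    lex = Lexicon()
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith(";;;"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise LexiconParseError(
                f"{source}:{lineno}: entry has no pronunciation: {line!r}")
        head, tokens = parts[0], parts[1:]
        alt = _ALT_RE.match(head)
        word = alt.group("word") if alt else head
        try:
            pron = tuple(strip_stress(t) for t in tokens)
        except LexiconParseError as exc:
            raise LexiconParseError(f"{source}:{lineno}: {exc}") from None
        lex.add(word, pron)
    return lex


def load_lexicon(path: str | Path) -> Lexicon:
    """Load a CMUDict 0.7b plain-text lexicon.

    Comments are skipped, alternates are grouped under the base word in
    file order, and stress digits are stripped. CMUDict 0.7b itself has a
    few non-UTF-8 bytes in comments, so decoding falls back to Latin-1.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError:
        text = path.read_text(encoding="latin-1")
    return _parse_lines(text.splitlines(), str(path))


_bundled: Lexicon | None = None


def bundled_lexicon() -> Lexicon:
    """The small fixture lexicon shipped with the package (cached)."""
    global _bundled
    if _bundled is None:
        ref = resources.files("phonalign.data") / "lexicon_fixture.txt"
        _bundled = _parse_lines(
            ref.read_text(encoding="utf-8").splitlines(), "lexicon_fixture.txt")
    return _bundled


def tokenize(text: str) -> list[str]:
    """Uppercase and split on whitespace, trimming edge punctuation.

    Internal apostrophes survive (CMUDict has entries like IT'S); numerals
    are not expanded and will surface as unresolved words downstream.
    """
    tokens = []
    for raw in text.upper().split():
        token = raw.strip(_EDGE_PUNCT)
        if token:
            tokens.append(token)
    return tokens


def transcribe(
    text: str,
    lexicon: Lexicon | None = None,
    overrides: Lexicon | None = None,
) -> PhonemeSequence:
    """Transcribe a sentence or word to a phoneme sequence.

    Each token is resolved against ``overrides`` first, then ``lexicon``,
    taking the first pronunciation; per-word phoneme lists are concatenated
    and word boundaries recorded. Raises :class:`UnresolvedWordError` for a
    token found in neither.
    """
    lexicon = lexicon if lexicon is not None else bundled_lexicon()
    phonemes: list[str] = []
    boundaries: list[int] = []
    for token in tokenize(text):
        if overrides is not None and token in overrides:
            pron = overrides.first(token)
        elif token in lexicon:
            pron = lexicon.first(token)
        else:
            raise UnresolvedWordError(token)
        boundaries.append(len(phonemes))
        phonemes.extend(pron)
    return PhonemeSequence(tuple(phonemes), tuple(boundaries))
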