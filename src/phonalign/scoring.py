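"""Per-phoneme accuracy scoring from alignments.

Each aligned column contributes to true-positive / false-positive /
false-negative tallies per phoneme: a match is a TP for that phoneme; a
deletion is a FN for the missed stimulus phoneme; an insertion is a FP for
the reported phoneme; a substitution is a FN for the stimulus phoneme and
a FP for the response phoneme. The per-phoneme F1 score (Sørensen–Dice
coefficient) is then 2·TP / (2·TP + FP + FN), the harmonic mean of
precision and sensitivity.

Session-level aggregation offers two conventions, because "averaged F1"
is ambiguous: ``mean_per_pair`` (default) averages the per-pair F1 over
the pairs in which the phoneme occurs at all; ``pooled`` sums TP/FP/FN
over pairs first and applies the F1 formula once. Both are reported as
percentages.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .align import Alignment
from .costs import OP_DEL, OP_INS, OP_MATCH, OP_SUB
from .phonemes import klass


@dataclass(frozen=True)
class PhonemeTally:
    """TP/FP/FN counts for one phoneme within one aligned pair."""

    phoneme: str
    tp: int
    fp: int
    fn: int

    @property
    def f1(self) -> float | None:
        """2TP/(2TP+FP+FN); None when the phoneme was never involved."""
        denom = 2 * self.tp + self.fp + self.fn
        if denom == 0:
            return None
        return 2 * self.tp / denom


def tally(alignment: Alignment) -> dict[str, PhonemeTally]:
    """Per-phoneme TP/FP/FN tallies for one aligned pair."""
    tp: dict[str, int] = defaultdict(int)
    fp: dict[str, int] = defaultdict(int)
    fn: dict[str, int] = defaultdict(int)
    for col in alignment.columns:
        if col.op == OP_MATCH:
            tp[col.stimulus] += 1
        elif col.op == OP_DEL:
            fn[col.stimulus] += 1
        elif col.op == OP_INS:
            fp[col.response] += 1
        elif col.op == OP_SUB:
            fn[col.stimulus] += 1
            fp[col.response] += 1
    out = {}
    for p in set(tp) | set(fp) | set(fn):
        out[p] = PhonemeTally(p, tp[p], fp[p], fn[p])
    return out


def correct_phoneme_count(alignment: Alignment) -> int:
    """Number of correct phonemes in the response (total TPs of the pair)."""
    return sum(1 for col in alignment.columns if col.op == OP_MATCH)


def aggregate(
    tallies: Iterable[Mapping[str, PhonemeTally]],
    mode: str = "mean_per_pair",
) -> dict[str, float]:
    """Session-level per-phoneme F1, as percentages in [0, 100].

    ``mean_per_pair`` averages each phoneme's per-pair F1 over the pairs
    where it occurs (in stimulus or response); ``pooled`` computes one F1
    from summed counts. Phonemes never observed are absent from the output.
    """
    tallies = list(tallies)
    if not tallies:
        raise ValueError("aggregate requires at least one scored pair")
    if mode == "mean_per_pair":
        sums: dict[str, float] = defaultdict(float)
        counts: dict[str, int] = defaultdict(int)
        for pair in tallies:
            for p, t in pair.items():
                f1 = t.f1
                if f1 is None:
                    continue
                sums[p] += f1
                counts[p] += 1
        return {p: 100.0 * sums[p] / counts[p] for p in sums}
    if mode == "pooled":
        tp: dict[str, int] = defaultdict(int)
        fp: dict[str, int] = defaultdict(int)
        fn: dict[str, int] = defaultdict(int)
        for pair in tallies:
            for p, t in pair.items():
                tp[p] += t.tp
                fp[p] += t.fp
                fn[p] += t.fn
        out = {}
        for p in set(tp) | set(fp) | set(fn):
            denom = 2 * tp[p] + fp[p] + fn[p]
            if denom:
                out[p] = 100.0 * 2 * tp[p] / denom
        return out
    raise ValueError(f"unknown aggregation mode: {mode!r}")


def score_table(
    tallies: Iterable[Mapping[str, PhonemeTally]],
    mode: str = "mean_per_pair",
) -> pd.DataFrame:
    """Tabular session summary: phoneme, class, counts, F1 percent, n pairs.

    Counts are pooled over pairs regardless of the F1 aggregation mode.
    """
    tallies = list(tallies)
    f1 = aggregate(tallies, mode)
    rows = []
    pooled: dict[str, list[int]] = defaultdict(lambda: [0, 0, 0, 0])
    for pair in tallies:
        for p, t in pair.items():
            pooled[p][0] += t.tp
            pooled[p][1] += t.fp
            pooled[p][2] += t.fn
            pooled[p][3] += 1
    for p in sorted(f1):
        tp, fp, fn, n_pairs = pooled[p]
        rows.append({
            "phoneme": p,
            "klass": klass(p),
            "TP": tp,
            "FP": fp,
            "FN": fn,
            "F1_percent": f1[p],
            "n_pairs": n_pairs,
        })
    return pd.DataFrame(rows)
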