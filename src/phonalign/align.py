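"""Minimum-edit-distance phoneme alignment with history-dependent costs.

Because every cost depends on the previous edit operation, the classic
two-index Levenshtein recurrence is not sufficient: the optimal way to
extend a partial alignment depends on which operation ended it, exactly as
in affine-gap sequence alignment. The engine therefore runs a three-state
dynamic programme over states {substitution-or-match, insertion, deletion}
(a match is a substitution in the zero tier, so the two share a state) and
charges the sequence start the no-switch column of the cost model. The
minimum edit distance (MED) is the optimal total cost.

Orientation follows the speech-test convention: an *insertion* aligns a
response phoneme with a gap in the stimulus (the listener reported a
phoneme that was not presented); a *deletion* aligns a stimulus phoneme
with a gap in the response (the listener missed it).

The DP is filled backwards (cost to complete the alignment from each cell
in each state), and co-optimal alignments are then enumerated by a forward
depth-first walk that takes operations in the canonical tie-break order —
substitution/match, then deletion, then insertion — so alignments stream
out in a documented, stable order and the first one is the canonical pick.
Ties in cost are detected with an absolute tolerance of 1e-9 (the table
costs are short exact decimals).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .costs import (
    CostModel,
    OP_DEL,
    OP_INS,
    OP_MATCH,
    OP_SUB,
    PREV_DEL,
    PREV_INS,
    PREV_SUB,
    classify_substitution,
    default_cost_model,
    op_cost,
)
from .features import FeatureTable, default_feature_table
from .phonemes import PhonemeSequence

GAP = None
TIE_TOL = 1e-9

_INF = float("inf")
# DP state indices; state of an operation == the operation just performed
_S_SUB, _S_INS, _S_DEL = 0, 1, 2
_PREV_OF_STATE = (PREV_SUB, PREV_INS, PREV_DEL)


@dataclass(frozen=True)
class AlignmentColumn:
    """One aligned slot: stimulus phoneme or gap, response phoneme or gap."""

    stimulus: str | None
    response: str | None
    op: str


@dataclass(frozen=True)
class Alignment:
    """An ordered gapped pairing of stimulus and response with its MED."""

    columns: tuple[AlignmentColumn, ...]
    total_cost: float

    @property
    def ops(self) -> tuple[str, ...]:
        return tuple(c.op for c in self.columns)

    def stimulus_phonemes(self) -> tuple[str, ...]:
        return tuple(c.stimulus for c in self.columns if c.stimulus is not None)

    def response_phonemes(self) -> tuple[str, ...]:
        return tuple(c.response for c in self.columns if c.response is not None)

    def recompute_cost(self, features: FeatureTable | None = None,
                       model: CostModel | None = None) -> float:
        """Re-derive total_cost column by column from the cost model."""
        features = features or default_feature_table()
        model = model or default_cost_model()
        prev = None
        total = 0.0
        for col in self.columns:
            if col.op in (OP_MATCH, OP_SUB):
                tier = classify_substitution(
                    col.stimulus, col.response, features, model)
                total += op_cost(OP_SUB, tier, prev, model)
                prev = PREV_SUB
            elif col.op == OP_DEL:
                total += op_cost(OP_DEL, None, prev, model)
                prev = PREV_DEL
            elif col.op == OP_INS:
                total += op_cost(OP_INS, None, prev, model)
                prev = PREV_INS
            else:
                raise ValueError(f"unknown op in alignment: {col.op!r}")
        return total


def _coerce(seq: Sequence[str] | PhonemeSequence) -> tuple[str, ...]:
    if isinstance(seq, PhonemeSequence):
        return seq.phonemes
    return tuple(seq)


class _Aligner:
    """Backward DP tables plus the canonical-order forward enumeration."""

    def __init__(self, stim: tuple[str, ...], resp: tuple[str, ...],
                 features: FeatureTable, model: CostModel):
        self.stim = stim
        self.resp = resp
        self.model = model
        m, n = len(stim), len(resp)
        self.m, self.n = m, n
        self.tier = [
            [classify_substitution(stim[i], resp[j], features, model)
             for j in range(n)]
            for i in range(m)
        ]
        # B[i][j][k]: least cost to align stim[i:] with resp[j:], given the
        # previous operation was state k. Filled bottom-up from (m, n).
        B = [[[_INF] * 3 for _ in range(n + 1)] for _ in range(m + 1)]
        for i in range(m, -1, -1):
            for j in range(n, -1, -1):
                for k in range(3):
                    B[i][j][k] = self._best_completion(B, i, j,
                                                       _PREV_OF_STATE[k])
        self.B = B

    def _moves(self, i: int, j: int, prev: str | None):
        """Feasible (op, step-cost, ni, nj, state) moves out of (i, j)."""
        model = self.model
        if i < self.m and j < self.n:
            c = model.substitution(self.tier[i][j], prev)
            yield OP_SUB, c, i + 1, j + 1, _S_SUB
        if i < self.m:
            yield OP_DEL, model.deletion(prev), i + 1, j, _S_DEL
        if j < self.n:
            yield OP_INS, model.insertion(prev), i, j + 1, _S_INS

    def _best_completion(self, B, i: int, j: int, prev: str | None) -> float:
        if i == self.m and j == self.n:
            return 0.0
        return min(c + B[ni][nj][k] for _, c, ni, nj, k in self._moves(i, j, prev))

    def med(self) -> float:
        return self._best_completion(self.B, 0, 0, None)

    def iter_scripts(self) -> Iterator[tuple[str, ...]]:
        """All co-optimal op sequences, in canonical order.

        Canonical order compares alignments column by column from the
        front, preferring substitution/match over deletion over insertion
        (the move order of ``_moves``).
        """
        B = self.B

        def walk(i: int, j: int, prev: str | None,
                 budget: float, acc: list[str]) -> Iterator[tuple[str, ...]]:
            if i == self.m and j == self.n:
                yield tuple(acc)
                return
            for opname, c, ni, nj, k in self._moves(i, j, prev):
                if abs(c + B[ni][nj][k] - budget) <= TIE_TOL:
                    acc.append(opname)
                    yield from walk(ni, nj, _PREV_OF_STATE[k],
                                    budget - c, acc)
                    acc.pop()

        yield from walk(0, 0, None, self.med(), [])


def _columns_from_ops(
    ops: Sequence[str],
    stim: tuple[str, ...],
    resp: tuple[str, ...],
) -> tuple[AlignmentColumn, ...]:
    cols = []
    i = j = 0
    for op in ops:
        if op == OP_SUB:
            s, r = stim[i], resp[j]
            cols.append(AlignmentColumn(s, r, OP_MATCH if s == r else OP_SUB))
            i += 1
            j += 1
        elif op == OP_DEL:
            cols.append(AlignmentColumn(stim[i], GAP, OP_DEL))
            i += 1
        else:
            cols.append(AlignmentColumn(GAP, resp[j], OP_INS))
            j += 1
    return tuple(cols)


def med(
    stimulus: Sequence[str] | PhonemeSequence,
    response: Sequence[str] | PhonemeSequence,
    features: FeatureTable | None = None,
    model: CostModel | None = None,
) -> float:
    """The minimum edit distance between a stimulus and a response."""
    stim, resp = _coerce(stimulus), _coerce(response)
    if not stim and not resp:
        return 0.0
    features = features or default_feature_table()
    model = model or default_cost_model()
    return _Aligner(stim, resp, features, model).med()


def align(
    stimulus: Sequence[str] | PhonemeSequence,
    response: Sequence[str] | PhonemeSequence,
    features: FeatureTable | None = None,
    model: CostModel | None = None,
) -> Alignment:
    """Optimal alignment of a stimulus/response pair.

    When several alignments are co-optimal this returns the canonical
    first: substitution/match preferred over deletion over insertion,
    decided column by column from the start of the pair.
    """
    alignments, _ = enumerate_optimal(stimulus, response, features, model, cap=1)
    return alignments[0]


def enumerate_optimal(
    stimulus: Sequence[str] | PhonemeSequence,
    response: Sequence[str] | PhonemeSequence,
    features: FeatureTable | None = None,
    model: CostModel | None = None,
    cap: int = 1000,
) -> tuple[list[Alignment], bool]:
    """All distinct co-optimal alignments, in canonical order.

    Returns ``(alignments, exhausted)``; ``exhausted`` is True when more
    than ``cap`` co-optimal alignments exist and the list was truncated
    at ``cap``.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    stim, resp = _coerce(stimulus), _coerce(response)
    features = features or default_feature_table()
    model = model or default_cost_model()
    if not stim and not resp:
        return [Alignment(columns=(), total_cost=0.0)], False
    engine = _Aligner(stim, resp, features, model)
    total = engine.med()
    out: list[Alignment] = []
    exhausted = False
    for ops in engine.iter_scripts():
        if len(out) == cap:
            exhausted = True
            break
        out.append(Alignment(columns=_columns_from_ops(ops, stim, resp),
                             total_cost=total))
    return out, exhausted


def count_optimal(
    stimulus: Sequence[str] | PhonemeSequence,
    response: Sequence[str] | PhonemeSequence,
    features: FeatureTable | None = None,
    model: CostModel | None = None,
    cap: int = 1000,
) -> tuple[int, bool]:
    """Number of co-optimal alignments (truncated at ``cap``)."""
    alignments, exhausted = enumerate_optimal(
        stimulus, response, features, model, cap)
    return len(alignments), exhausted


def align_pairs(
    pairs: Iterable[tuple[Sequence[str] | PhonemeSequence,
                          Sequence[str] | PhonemeSequence]],
    features: FeatureTable | None = None,
    model: CostModel | None = None,
) -> list[Alignment]:
    """Align every (stimulus, response) pair with shared tables."""
    features = features or default_feature_table()
    model = model or default_cost_model()
    return [align(s, r, features, model) for s, r in pairs]
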