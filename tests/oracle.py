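"""Brute-force reference for history-dependent edit distance.

Enumerates every monotone edit script transforming a stimulus into a
response (all interleavings of substitutions, deletions and insertions
that consume both sequences) and prices each column with the cost model,
given the actual previous operation. Exponential, so only usable on short
sequences — which is the point: it is independent of the dynamic
programme it checks.
"""

from __future__ import annotations

from phonalign.costs import (CostModel, OP_DEL, OP_INS, OP_SUB, PREV_DEL,
                             PREV_INS, PREV_SUB, classify_substitution)
from phonalign.features import FeatureTable

_PREV = {OP_SUB: PREV_SUB, OP_INS: PREV_INS, OP_DEL: PREV_DEL}


def all_scripts(m: int, n: int):
    """Every op sequence consuming m stimulus and n response symbols."""
    if m == 0 and n == 0:
        yield ()
        return
    if m > 0 and n > 0:
        for rest in all_scripts(m - 1, n - 1):
            yield (OP_SUB,) + rest
    if m > 0:
        for rest in all_scripts(m - 1, n):
            yield (OP_DEL,) + rest
    if n > 0:
        for rest in all_scripts(m, n - 1):
            yield (OP_INS,) + rest


def script_cost(ops, stim, resp, features: FeatureTable,
                model: CostModel) -> float:
    i = j = 0
    prev = None
    total = 0.0
    for op in ops:
        if op == OP_SUB:
            tier = classify_substitution(stim[i], resp[j], features, model)
            total += model.substitution(tier, prev)
            i += 1
            j += 1
        elif op == OP_DEL:
            total += model.deletion(prev)
            i += 1
        else:
            total += model.insertion(prev)
            j += 1
        prev = _PREV[op]
    return total


def optimal_scripts(stim, resp, features: FeatureTable, model: CostModel,
                    tol: float = 1e-9):
    """(min cost, set of co-optimal op sequences) by full enumeration."""
    best = float("inf")
    scored = []
    for ops in all_scripts(len(stim), len(resp)):
        c = script_cost(ops, stim, resp, features, model)
        scored.append((c, ops))
        if c < best:
            best = c
    winners = {ops for c, ops in scored if abs(c - best) <= tol}
    return best, winners
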