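"""Edit-operation cost model with history-dependent, similarity-tiered costs.

The alignment engine charges each operation a cost that depends on (a) the
operation itself, (b) for substitutions, the phonological similarity tier
of the stimulus/response phoneme pair, and (c) the previous operation in
the edit script. The history dependence penalises switching between gap
runs (insertions/deletions) and substitution runs, which is what keeps
response phonemes from being scattered across distant stimulus positions;
the similarity tiers prefer substitutions between phonemes that plausibly
confuse (voicing cognates like F/V, same-manner consonants like K/P,
near-identical vowels).

Tiers, from most to least penalised:

  vowel_consonant > consonant_consonant > same_manner_consonant
  > similar_consonant > vowel_vowel > similar_vowel > match
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .features import FeatureTable, default_feature_table
from .phonemes import is_vowel, validate

# Substitution tiers
MATCH = "match"
SIMILAR_VOWEL = "similar_vowel"
VOWEL_VOWEL = "vowel_vowel"
SIMILAR_CONSONANT = "similar_consonant"
SAME_MANNER_CONSONANT = "same_manner_consonant"
CONSONANT_CONSONANT = "consonant_consonant"
VOWEL_CONSONANT = "vowel_consonant"

TIERS: tuple[str, ...] = (
    MATCH, SIMILAR_VOWEL, VOWEL_VOWEL, SIMILAR_CONSONANT,
    SAME_MANNER_CONSONANT, CONSONANT_CONSONANT, VOWEL_CONSONANT,
)

# Edit operations (match is the zero-cost tier of substitution but is
# reported as its own op in alignments).
OP_MATCH = "match"
OP_SUB = "substitution"
OP_INS = "insertion"
OP_DEL = "deletion"

# Previous-operation categories for cost lookup. A previous match counts
# as a previous substitution.
PREV_SUB = "sub"
PREV_INS = "ins"
PREV_DEL = "del"
PREV_NONE = None


@dataclass(frozen=True)
class CostModel:
    """All edit costs, indexed by (operation, tier, previous operation).

    ``ins_cost``/``del_cost`` map previous-op -> cost; ``sub_cost`` maps
    tier -> (cost after substitution, after insertion, after deletion).
    At the start of a sequence the no-switch column applies.
    """

    ins_cost: dict[str, float]
    del_cost: dict[str, float]
    sub_cost: dict[str, tuple[float, float, float]]
    similar_consonant_pairs: frozenset[frozenset[str]] = field(
        default_factory=frozenset)
    similar_vowel_max_differences: int = 1

    def insertion(self, prev: str | None) -> float:
        if prev is None or prev == PREV_INS:
            return self.ins_cost[PREV_INS]
        return self.ins_cost[prev]

    def deletion(self, prev: str | None) -> float:
        if prev is None or prev == PREV_DEL:
            return self.del_cost[PREV_DEL]
        return self.del_cost[prev]

    def substitution(self, tier: str, prev: str | None) -> float:
        after_sub, after_ins, after_del = self.sub_cost[tier]
        if prev is None or prev == PREV_SUB:
            return after_sub
        if prev == PREV_INS:
            return after_ins
        if prev == PREV_DEL:
            return after_del
        raise ValueError(f"unknown previous operation: {prev!r}")


def classify_substitution(
    a: str,
    b: str,
    features: FeatureTable | None = None,
    model: "CostModel | None" = None,
) -> str:
    """Similarity tier for substituting response phoneme *b* for stimulus *a*.

    Matches are tier ``match``; cross-class pairs are ``vowel_consonant``;
    vowel pairs are ``similar_vowel`` when they differ in at most the
    model's allowed number of features, else ``vowel_vowel``; consonant
    pairs are ``similar_consonant`` when listed as cognates in the model,
    else ``same_manner_consonant`` when their manner subtypes agree, else
    ``consonant_consonant``.
    """
    features = features or default_feature_table()
    model = model or default_cost_model()
    validate(a)
    validate(b)
    if a == b:
        return MATCH
    a_vowel, b_vowel = is_vowel(a), is_vowel(b)
    if a_vowel != b_vowel:
        return VOWEL_CONSONANT
    if a_vowel:
        ndiff = features.n_feature_differences(a, b)
        if ndiff <= model.similar_vowel_max_differences:
            return SIMILAR_VOWEL
        return VOWEL_VOWEL
    if frozenset((a, b)) in model.similar_consonant_pairs:
        return SIMILAR_CONSONANT
    if features.value(a, "manner") == features.value(b, "manner"):
        return SAME_MANNER_CONSONANT
    return CONSONANT_CONSONANT


def op_cost(
    op: str,
    tier: str | None,
    prev: str | None,
    model: "CostModel | None" = None,
) -> float:
    """Cost of one edit operation given the previous operation.

    ``tier`` is required for substitution/match ops and forbidden otherwise;
    ``prev`` is one of ``"sub"``, ``"ins"``, ``"del"`` or ``None`` (sequence
    start).
    """
    model = model or default_cost_model()
    if op in (OP_SUB, OP_MATCH):
        if tier is None:
            tier = MATCH if op == OP_MATCH else None
        if tier is None:
            raise ValueError("substitution cost requires a similarity tier")
        return model.substitution(tier, prev)
    if tier is not None:
        raise ValueError(f"{op} takes no similarity tier")
    if op == OP_INS:
        return model.insertion(prev)
    if op == OP_DEL:
        return model.deletion(prev)
    raise ValueError(f"unknown operation: {op!r}")


def load_cost_model(path: str | Path | None = None) -> CostModel:
    """Load a cost model from YAML; the bundled defaults when path is None."""
    if path is None:
        ref = resources.files("phonalign.data") / "costs.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    pairs = frozenset(
        frozenset(p) for p in raw.get("similar_consonant_pairs", []))
    sub = {
        tier: tuple(float(c) for c in costs)
        for tier, costs in raw["substitution"].items()
    }
    missing = set(TIERS) - set(sub)
    if missing:
        raise ValueError(f"cost file missing substitution tiers: {missing}")
    return CostModel(
        ins_cost={PREV_INS: float(raw["insertion"]["prev_ins"]),
                  PREV_SUB: float(raw["insertion"]["prev_sub"]),
                  PREV_DEL: float(raw["insertion"]["prev_del"])},
        del_cost={PREV_INS: float(raw["deletion"]["prev_ins"]),
                  PREV_SUB: float(raw["deletion"]["prev_sub"]),
                  PREV_DEL: float(raw["deletion"]["prev_del"])},
        sub_cost=sub,
        similar_consonant_pairs=pairs,
        similar_vowel_max_differences=int(
            raw.get("similar_vowel_max_differences", 1)),
    )


_default: CostModel | None = None


def default_cost_model() -> CostModel:
    """The bundled history-dependent, similarity-tiered cost model (cached)."""
    global _default
    if _default is None:
        _default = load_cost_model()
    return _default


def make_simple_cost_model() -> CostModel:
    """The legacy history-independent model: indel 1, substitution 2, match 0.

    Kept for regression comparisons; it tends to admit many co-optimal
    alignments where the default model admits one.
    """
    return CostModel(
        ins_cost={PREV_INS: 1.0, PREV_SUB: 1.0, PREV_DEL: 1.0},
        del_cost={PREV_INS: 1.0, PREV_SUB: 1.0, PREV_DEL: 1.0},
        sub_cost={tier: (2.0, 2.0, 2.0) for tier in TIERS}
        | {MATCH: (0.0, 0.0, 0.0)},
        similar_consonant_pairs=frozenset(),
        similar_vowel_max_differences=1,
    )
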