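"""Confusion matrices, information transfer, and phonemegram limits."""

import math

import numpy as np
import pytest

from phonalign.align import align
from phonalign.features import ALL_FEATURES
from phonalign.infotransfer import (ConfusionMatrix, FeatureMatrix,
                                    build_confusion, collapse_feature,
                                    information_transfer, phonemegram,
                                    response_entropy, stimulus_entropy)
from phonalign.phonemes import CONSONANTS, VOWELS

FUN, THIN = ["F", "AH", "N"], ["TH", "IH", "N"]


def _identity_matrices():
    cons = ConfusionMatrix.empty("consonant")
    vows = ConfusionMatrix.empty("vowel")
    for p in CONSONANTS:
        cons.increment(p, p)
    for p in VOWELS:
        vows.increment(p, p)
    return cons, vows


class TestBuildConfusion:
    def test_shapes(self):
        cons, vows = build_confusion([])
        assert cons.counts.shape == (24, 25)
        assert vows.counts.shape == (15, 16)

    def test_worked_alignment_routing(self, features, model):
        a = align(FUN, THIN, features, model)
        cons, vows = build_confusion([a])
        assert cons.to_frame().loc["F", "TH"] == 1
        assert cons.to_frame().loc["N", "N"] == 1
        assert vows.to_frame().loc["AH", "IH"] == 1
        assert cons.counts.sum() == 2 and vows.counts.sum() == 1

    def test_empty_response_fills_unclassified(self, features, model):
        stim = ["B", "UH", "K", "S"]
        a = align(stim, [], features, model)
        cons, vows = build_confusion([a])
        assert cons.to_frame()["unclassified"].sum() == 3
        assert vows.to_frame()["unclassified"].sum() == 1
        assert cons.counts.sum() + vows.counts.sum() == 4

    def test_row_sums_count_stimulus_occurrences(self, features, model):
        a = align(FUN, THIN, features, model)
        cons, _ = build_confusion([a])
        assert cons.to_frame().loc["F"].sum() == 1
        assert cons.to_frame().loc["N"].sum() == 1


class TestCollapseFeature:
    def test_subtype_grouping_shape(self):
        _, vows = _identity_matrices()
        fm = collapse_feature(vows, "vowel_height")
        assert fm.counts.shape == (3, 4)  # 3 subtypes + unclassified
        assert fm.n == len(VOWELS)

    def test_diagonal_collapses_to_diagonal(self):
        cons, _ = _identity_matrices()
        fm = collapse_feature(cons, "voicing")
        body = fm.counts[:, :-1]
        assert (body == np.diag(np.diag(body))).all()
        assert fm.counts[:, -1].sum() == 0

    def test_voicing_routing_of_f_to_v(self, features):
        cons = ConfusionMatrix.empty("consonant")
        cons.increment("F", "V")
        fm = collapse_feature(cons, "voicing", features)
        # F is unvoiced (0), V voiced (1) in the shipped table
        assert fm.to_frame().loc[0, 1] == 1
        assert fm.n == 1

    def test_count_conservation(self, features, model):
        a = align(FUN, THIN, features, model)
        cons, vows = build_confusion([a])
        for feature in ALL_FEATURES:
            matrix = vows if feature.startswith(("vowel", "contour")) else cons
            fm = collapse_feature(matrix, feature, features)
            assert fm.n == matrix.counts.sum()

    def test_class_mismatch_rejected(self):
        cons, _ = _identity_matrices()
        with pytest.raises(ValueError):
            collapse_feature(cons, "vowel_height")


class TestInformationTransfer:
    def test_identity_gives_full_relative_transfer(self):
        cons, vows = _identity_matrices()
        pg = phonemegram(cons, vows)
        defined = pg.dropna(subset=["relative_percent"])
        assert len(defined) == len(ALL_FEATURES)
        assert np.allclose(defined["relative_percent"], 100.0)

    def test_rank_one_matrix_zero_it(self):
        fm = FeatureMatrix("voicing", [0, 1], [0, 1],
                           np.outer([3, 6], [2, 4]) // 2)
        res = information_transfer(fm)
        assert res.it == pytest.approx(0.0, abs=1e-9)
        assert res.relative == pytest.approx(0.0, abs=1e-9)

    def test_all_unclassified_zero_it(self, features, model):
        stim = ["B", "UH", "K", "S", "M", "IY"]
        a = align(stim, [], features, model)
        cons, vows = build_confusion([a])
        pg = phonemegram(cons, vows, features)
        defined = pg.dropna(subset=["relative_percent"])
        assert np.allclose(defined["relative_percent"], 0.0, atol=1e-9)

    def test_voicing_margin_example(self):
        assert stimulus_entropy([7, 9], base=2) == pytest.approx(0.9887,
                                                                 abs=5e-5)

    def test_it_identity_and_bounds(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.integers(0, 8, size=(3, 4))
            if counts.sum() == 0:
                continue
            fm = FeatureMatrix("manner", [0, 1, 2], [0, 1, 2, "unclassified"],
                               counts)
            res = information_transfer(fm)
            n = counts.sum()
            assert res.it == pytest.approx(res.hx + res.hy - res.hxy)
            assert -1e-9 <= res.it <= min(res.hx, res.hy) + 1e-9
            assert min(res.hx, res.hy) <= math.log(n) + 1e-9
            assert res.hstim == pytest.approx(res.hx)

    def test_it_label_permutation_invariant(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 10, size=(3, 4))
        fm = FeatureMatrix("manner", [0, 1, 2], list(range(4)), counts)
        perm = counts[:, [2, 0, 3, 1]]
        fm2 = FeatureMatrix("manner", [0, 1, 2], list(range(4)), perm)
        assert information_transfer(fm2).it == pytest.approx(
            information_transfer(fm).it)

    def test_merging_response_columns_never_increases_it(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            counts = rng.integers(0, 10, size=(3, 4))
            if counts.sum() == 0:
                continue
            merged = np.column_stack([counts[:, 0] + counts[:, 1],
                                      counts[:, 2], counts[:, 3]])
            it_full = information_transfer(
                FeatureMatrix("f", [0, 1, 2], list(range(4)), counts)).it
            it_merged = information_transfer(
                FeatureMatrix("f", [0, 1, 2], list(range(3)), merged)).it
            assert it_merged <= it_full + 1e-9

    def test_relative_it_is_log_base_invariant(self):
        """Scaling all entropies by a common log base cancels in IT/Hstim."""
        counts = np.array([[5, 1, 0], [2, 7, 1]])
        fm = FeatureMatrix("voicing", [0, 1], [0, 1, "unclassified"], counts)
        res = information_transfer(fm)
        it_bits = res.it / math.log(2)
        hstim_bits = stimulus_entropy(counts.sum(axis=1), base=2)
        assert it_bits / hstim_bits == pytest.approx(res.relative)

    def test_zero_n_rejected(self):
        fm = FeatureMatrix("voicing", [0, 1], [0, 1],
                           np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError):
            information_transfer(fm)

    def test_single_subtype_reported_undefined(self, features, model):
        # a nasal-free stimulus set: nasality has one presented subtype
        a = align(["B", "D"], ["B", "D"], features, model)
        cons, vows = build_confusion([a])
        pg = phonemegram(cons, vows, features).set_index("feature")
        assert np.isnan(pg.loc["nasality", "relative_percent"])


class TestPhonemegram:
    def test_band_assignment(self):
        cons, vows = _identity_matrices()
        pg = phonemegram(cons, vows).set_index("feature")
        assert pg.loc["voicing", "band"] == "low"
        assert pg.loc["sibilance", "band"] == "high"
        assert pg.loc["vowel_place", "band"] == "mid_vowel"
        assert pg.loc["affrication", "band"] == "mid_consonant"
        assert list(pg.index) == list(ALL_FEATURES)

    def test_within_subtype_substitutions_keep_feature_perfect(
            self, features, model):
        """Phoneme errors confined inside one subtype leave that feature
        at 100% even though phoneme accuracy drops."""
        # IY <-> IH confusions: distinct vowels, but identical vowel_place
        cons, vows = build_confusion([
            align(["IY"], ["IH"], features, model),
            align(["IH"], ["IY"], features, model),
            align(["AA"], ["AA"], features, model),
        ])
        pg = phonemegram(cons, vows, features).set_index("feature")
        assert pg.loc["vowel_place", "relative_percent"] == \
            pytest.approx(100.0)


class TestResponseEntropy:
    def test_always_correct_phoneme_zero_bits(self):
        cons, vows = _identity_matrices()
        ent = response_entropy(cons, vows)
        assert set(ent) == set(CONSONANTS) | set(VOWELS)
        assert all(v == pytest.approx(0.0) for v in ent.values())

    def test_two_equal_outcomes_one_bit(self):
        cons = ConfusionMatrix.empty("consonant")
        cons.increment("F", "TH")
        cons.increment("F", "F")
        ent = response_entropy(cons, ConfusionMatrix.empty("vowel"))
        assert ent["F"] == pytest.approx(1.0)
        assert "K" not in ent

    def test_uniform_row_hits_log2_of_categories(self):
        cons = ConfusionMatrix.empty("consonant")
        cons.counts[0, :] = 1  # uniform over 25 response categories
        ent = response_entropy(cons, ConfusionMatrix.empty("vowel"))
        assert ent["B"] == pytest.approx(math.log2(25))
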