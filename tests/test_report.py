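"""Rendering and the command-line interface."""

import numpy as np
import pytest
from click.testing import CliRunner

from phonalign.align import align
from phonalign.cli import main
from phonalign.report import f1_grid_data, render_alignment, render_f1_grids
from phonalign.synth import CorruptionSpec, make_corpus, write_pairs_tsv

FUN, THIN = ["F", "AH", "N"], ["TH", "IH", "N"]


class TestRenderAlignment:
    def test_three_substitution_pair(self, features, model):
        text = render_alignment(align(FUN, THIN, features, model))
        lines = text.splitlines()
        assert lines[0].split() == ["F", "AH", "N"]
        assert lines[1].split() == ["TH", "IH", "N"]
        assert lines[2].split() == ["S", "S", "M"]
        assert "MED: 2.2" in text

    def test_identity_all_matches(self, features, model):
        text = render_alignment(align(FUN, FUN, features, model))
        assert text.splitlines()[2].split() == ["M", "M", "M"]

    def test_empty_response_all_deletions(self, features, model):
        text = render_alignment(align(FUN, [], features, model))
        lines = text.splitlines()
        assert lines[1].split() == ["-", "-", "-"]
        assert lines[2].split() == ["D", "D", "D"]

    def test_gap_slots_align_with_ops(self, features, model):
        text = render_alignment(align(["K", "B"], ["K", "K", "B"],
                                      features, model))
        lines = text.splitlines()
        assert lines[0].split().count("-") == 1
        assert lines[2].split().count("I") == 1


class TestF1Grids:
    def test_coordinates_follow_feature_subtypes(self, features):
        data = f1_grid_data({"IY": 80.0, "B": 50.0, "K": 10.0}, features)
        data = data.set_index("phoneme")
        assert data.loc["IY", "panel"] == "vowels"
        assert (data.loc["IY", "x"], data.loc["IY", "y"]) == (0, 2)
        assert data.loc["B", "panel"] == "voiced_consonants"
        assert data.loc["K", "panel"] == "unvoiced_consonants"
        assert (data.loc["K", "x"], data.loc["K", "y"]) == (2, 0)

    def test_absent_phonemes_absent_from_grid(self, features):
        data = f1_grid_data({"IY": 100.0}, features)
        assert list(data["phoneme"]) == ["IY"]

    def test_all_correct_session_uniform_100(self, features):
        f1 = {p: 100.0 for p in ("IY", "B", "K", "S")}
        fig, data = render_f1_grids(f1, features)
        assert (data["f1_percent"] == 100.0).all()

    def test_single_failed_phoneme_stands_out(self, features, model):
        from phonalign.scoring import aggregate, tally
        # F is always missed; everything else always correct
        tallies = [tally(align(["F", "AH", "N"], ["AH", "N"],
                               features, model))]
        data = f1_grid_data(aggregate(tallies), features)
        data = data.set_index("phoneme")
        assert data.loc["F", "f1_percent"] == 0.0
        assert data.loc["N", "f1_percent"] == 100.0


def test_render_phonemegram_handles_undefined_features(features, model):
    from phonalign.infotransfer import build_confusion, phonemegram
    from phonalign.report import render_phonemegram
    a = align(["B", "D"], ["B", "D"], features, model)  # nasality undefined
    pg = phonemegram(*build_confusion([a]), features)
    fig = render_phonemegram(pg)
    assert len(fig.axes[0].patches) >= 10


class TestCli:
    def test_transcribe(self):
        result = CliRunner().invoke(main, ["transcribe", "fun"])
        assert result.exit_code == 0
        assert result.output.strip() == "F AH N"

    def test_transcribe_unresolved_word_fails(self):
        result = CliRunner().invoke(main, ["transcribe", "zzxq"])
        assert result.exit_code != 0
        assert "ZZXQ" in result.output

    def test_align_bundled_example_pairs(self):
        from importlib import resources
        ref = resources.files("phonalign.data") / "example_pairs.tsv"
        with resources.as_file(ref) as path:
            result = CliRunner().invoke(main, ["align", str(path)])
        assert result.exit_code == 0, result.output
        assert "MED: 2.2" in result.output   # fun / thin
        assert "MED: 0" in result.output     # key / key

    def test_align_reports_worked_example_med(self, tmp_path):
        pair_file = tmp_path / "pairs.tsv"
        pair_file.write_text("id\tstimulus\tresponse\n1\tfun\tthin\n")
        result = CliRunner().invoke(main, ["align", str(pair_file)])
        assert result.exit_code == 0
        assert "MED: 2.2" in result.output

    def test_align_unresolved_word_lists_token(self, tmp_path):
        pair_file = tmp_path / "pairs.tsv"
        pair_file.write_text("id\tstimulus\tresponse\n1\tfun\tkints\n")
        result = CliRunner().invoke(main, ["align", str(pair_file)])
        assert result.exit_code != 0
        assert "KINTS" in result.output

    def test_align_with_override_lexicon(self, tmp_path):
        pair_file = tmp_path / "pairs.tsv"
        pair_file.write_text("id\tstimulus\tresponse\n1\tpinch\tkints\n")
        override = tmp_path / "override.txt"
        override.write_text("KINTS  K IH1 N T S\n")
        result = CliRunner().invoke(
            main, ["align", str(pair_file), "--overrides", str(override)])
        assert result.exit_code == 0, result.output

    def test_analyze_zero_corruption_all_f1_100(self, tmp_path):
        pairs = make_corpus(6, CorruptionSpec(p_sub=0, p_del=0, p_ins=0,
                                              seed=4))
        pair_file = tmp_path / "pairs.tsv"
        write_pairs_tsv(pair_file, pairs)
        outdir = tmp_path / "out"
        result = CliRunner().invoke(main, [
            "analyze", str(pair_file), "--phonemic", "--no-plots",
            "--out", str(outdir)])
        assert result.exit_code == 0, result.output
        import pandas as pd
        table = pd.read_csv(outdir / "f1_scores.csv")
        assert (table["F1_percent"] == 100.0).all()
        pg = pd.read_csv(outdir / "phonemegram.csv")
        defined = pg.dropna(subset=["relative_percent"])
        assert np.allclose(defined["relative_percent"], 100.0)

    def test_simulate_then_validate_roundtrip(self, tmp_path):
        pair_file = tmp_path / "synthetic.tsv"
        result = CliRunner().invoke(main, [
            "simulate", "--n-pairs", "12", "--seed", "5",
            "--out", str(pair_file)])
        assert result.exit_code == 0, result.output
        outdir = tmp_path / "val"
        result = CliRunner().invoke(main, [
            "validate", str(pair_file), "--phonemic", "--seed", "5",
            "--out", str(outdir)])
        assert result.exit_code == 0, result.output
        import pandas as pd
        hist = pd.read_csv(outdir / "correct_phoneme_histogram.csv")
        assert hist["actual_pairs"].sum() == 12
        assert hist["deranged_pairs"].sum() == 12
        for name in ("phoneme_entropy.csv", "phonemegram_actual.csv",
                     "phonemegram_deranged.csv"):
            assert (outdir / name).exists()
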