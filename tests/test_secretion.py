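"""Signal-peptide heuristic, topology scan, ER retention and the funnel."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from sspmine.config import DEFAULT_CONFIG
from sspmine.errors import (
    DegenerateCleavageError,
    MissingPredictionError,
    SequenceTooShortError,
    TableParseError,
)
from sspmine.proteome import ProteinRecord
from sspmine.secretion import (
    SignalPeptideCall,
    TopologyCall,
    detect_tm_builtin,
    er_retention,
    load_external_sp_calls,
    load_external_tm_calls,
    mature_sequence,
    predict_signal_peptide_builtin,
    secretion_pipeline,
)
from sspmine.synthetic import ProteomeCounts, funnel_expectation, generate_proteome


class TestSignalPeptideHeuristic:
    def test_constructed_positive_cleaves_at_first_qualifying_site(self):
        # M K L8 (h-region 3-10) N Q D E (spacer) A T A -> first (p, p-2)
        # small-residue pair is (17, 15): cleavage after 17.
        seq = "MK" + "L" * 8 + "NQDE" + "ATA" + "DDDDDDDDDD"
        call = predict_signal_peptide_builtin(seq)
        assert call.has_sp
        assert call.cleavage_after == 17
        assert call.score == 1.0  # 8/8 hydrophobic core

    def test_weak_h_region_never_fires(self):
        # only 5 hydrophobic residues in any 8-window
        seq = "MK" + "LLNLLNLN" + "NQDE" + "ATA" + "DDDDDDDDDD"
        assert not predict_signal_peptide_builtin(seq).has_sp

    def test_no_hydrophobic_window_negative(self):
        assert not predict_signal_peptide_builtin("MDDDEEEKKKRRRNNNQQQSSS").has_sp

    def test_h_region_without_small_residue_site_negative(self):
        # poly-L satisfies the h-region but offers no (-3,-1) pair
        assert not predict_signal_peptide_builtin("M" + "L" * 39).has_sp

    def test_c_site_requires_two_residue_offset_from_h_window(self):
        # h-window only at positions 18-25 (ends 25); a small-residue pair at
        # p=15 exists but no h-window ends by p-2=13, so the first licensed
        # cleavage is p >= 27.
        seq = "MDDDDDDDDDDDDATA" + "NL" + "LLLLLLL" + "DA" + "TA" + "DDDDDD"
        call = predict_signal_peptide_builtin(seq)
        assert call.has_sp
        assert call.cleavage_after >= 27

    def test_short_sequence_is_a_no_call_error(self):
        with pytest.raises(SequenceTooShortError):
            predict_signal_peptide_builtin("MKTLLVLALLLALA")  # 14 residues


class TestTopologyScan:
    def test_leucine_stretch_called(self):
        call = detect_tm_builtin("S" * 30 + "L" * 19 + "S" * 30)
        assert call.has_tm
        start, end, mean = call.best_window
        assert (start, end) == (31, 49)
        assert mean == pytest.approx(3.8)

    def test_polar_sequence_negative(self):
        call = detect_tm_builtin("S" * 19)
        assert not call.has_tm
        assert call.best_window[2] == pytest.approx(-0.8)

    def test_shorter_than_window_negative_with_no_window(self):
        call = detect_tm_builtin("LLLLLLLLLL")  # 10 < 19
        assert not call.has_tm
        assert call.best_window is None

    def test_tie_goes_to_leftmost_window(self):
        call = detect_tm_builtin("L" * 25)  # all windows identical
        assert call.best_window[0] == 1


class TestErRetention:
    @pytest.mark.parametrize("seq,expected", [
        ("MGGAAKDEL", True),
        ("MGGAAHDEL", True),
        ("MGGKDELA", False),   # motif not terminal
        ("MGGRDEL", False),
    ])
    def test_terminal_tetrapeptide(self, seq, expected):
        assert er_retention(seq) is expected

    def test_short_sequence_warns_false(self):
        with pytest.warns(UserWarning):
            assert er_retention("KDE") is False

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=5, max_size=60),
           st.integers(0, 1_000_000), st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
    def test_depends_only_on_final_four_residues(self, seq, pos, res):
        mutated = list(seq)
        mutated[pos % (len(seq) - 4)] = res  # never touches the last 4
        assert er_retention(seq) == er_retention("".join(mutated))


class TestMatureSequence:
    def test_slicing(self):
        call = SignalPeptideCall(True, cleavage_after=25, score=1.0)
        assert len(mature_sequence("M" * 100, call)) == 75

    def test_cleavage_at_terminus_is_degenerate(self):
        call = SignalPeptideCall(True, cleavage_after=10, score=1.0)
        with pytest.raises(DegenerateCleavageError):
            mature_sequence("M" * 10, call)

    def test_mature_begins_after_cleavage(self):
        seq = "MKT" + "A" * 22 + "DYYSAQQ"
        call = SignalPeptideCall(True, cleavage_after=25, score=1.0)
        assert mature_sequence(seq, call) == "DYYSAQQ"


class TestExternalAdapters:
    def test_sp_short_format(self, tmp_path):
        table = tmp_path / "sp.tsv"
        table.write_text("g1\tSP(Sec/SPI)\tCS pos: 24-25\ng2\tOTHER\n")
        calls = load_external_sp_calls(table)
        assert calls["g1"] == SignalPeptideCall(True, 24, 1.0, "external-file")
        assert not calls["g2"].has_sp

    def test_conflicting_duplicate_refused(self, tmp_path):
        table = tmp_path / "sp.tsv"
        table.write_text("g1\tSP(Sec/SPI)\tCS pos: 24-25\ng1\tOTHER\n")
        with pytest.raises(TableParseError, match="conflicting"):
            load_external_sp_calls(table)

    def test_malformed_row_reports_line(self, tmp_path):
        table = tmp_path / "sp.tsv"
        table.write_text("g1\tSP(Sec/SPI)\tCS pos: 24-25\njust-an-id\n")
        with pytest.raises(TableParseError, match="line 2"):
            load_external_sp_calls(table)

    def test_tm_counts(self, tmp_path):
        table = tmp_path / "tm.tsv"
        table.write_text("g1\t0\ng2\t3\n")
        calls = load_external_tm_calls(table)
        assert not calls["g1"].has_tm
        assert calls["g2"].has_tm


class TestSecretionPipeline:
    def test_truth_fed_funnel_recovers_planted_set_exactly(self, registry, config):
        proteome = generate_proteome(seed=11, registry=registry, config=config)
        candidates, verdicts, counts = secretion_pipeline(
            proteome.records, proteome.sp_calls, proteome.tm_calls, config
        )
        assert counts == funnel_expectation(proteome.truth)
        planted = {g for g, t in proteome.truth.items() if t.category == "planted_ssp"}
        assert {r.gene_id for r in candidates} == planted

    def test_empty_input(self):
        candidates, verdicts, counts = secretion_pipeline([])
        assert candidates == [] and verdicts == []
        assert counts["input"] == 0 and counts["truncation"] == 0

    def test_single_planted_ssp_survives_every_stage(self, registry, config):
        proteome = generate_proteome(
            counts=ProteomeCounts(1, 0, 0, 0, 0, 0),
            seed=5, registry=registry, config=config,
        )
        _, _, counts = secretion_pipeline(
            proteome.records, proteome.sp_calls, proteome.tm_calls, config
        )
        assert all(v == 1 for v in counts.values())

    def test_stages_non_increasing_and_first_failure_recorded(self, registry, config):
        proteome = generate_proteome(seed=13, registry=registry, config=config)
        _, verdicts, counts = secretion_pipeline(
            proteome.records, proteome.sp_calls, proteome.tm_calls, config
        )
        ordered = list(counts.values())
        assert all(a >= b for a, b in zip(ordered, ordered[1:]))
        for v in verdicts:
            failed = [r.stage for r in v.stage_results if r.passed is False]
            if failed:
                assert v.rejected_at == failed[0]
                # nothing after the first failure was evaluated
                seen_fail = False
                for r in v.stage_results:
                    if seen_fail:
                        assert r.passed is None
                    if r.passed is False:
                        seen_fail = True

    def test_missing_external_call_is_a_hard_error(self, config):
        rec = ProteinRecord("G1", "G1.1", "M" * 30)
        with pytest.raises(MissingPredictionError):
            secretion_pipeline([rec], {}, {}, config)

    def test_missing_negative_mode_rejects_at_sp(self, config):
        rec = ProteinRecord("G1", "G1.1", "M" * 30)
        _, verdicts, _ = secretion_pipeline([rec], {}, {}, config, missing="negative")
        assert verdicts[0].rejected_at == "signal_peptide"
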