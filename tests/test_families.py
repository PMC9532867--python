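"""Family registry, classification, CEP/PIP disambiguation, cysteine profiling."""

import pytest
import yaml

from sspmine.errors import RegistryValidationError
from sspmine.families import (
    CysteineProfile,
    classify_family,
    crp_spectrum,
    cysteine_profile,
    disambiguate_cep_pip,
    load_family_registry,
    registry_summary,
)
from sspmine.secretion import SignalPeptideCall
from sspmine.synthetic import generate_proteome

from tests._oracles import CEP_PIP_ORACLE


class TestRegistry:
    def test_packaged_registry_holds_38_families(self, registry):
        assert len(registry) == 38

    def test_cep_entry_matches_reported_metadata(self, registry):
        cep = registry["CEP"]
        assert cep.reported_wheat_count == 13
        assert cep.peptide_class == "PTM"
        assert cep.mode_of_action == ("Signal",)

    def test_reported_counts(self, registry):
        assert registry["CLE"].reported_wheat_count == 88
        assert registry["nsLTP"].reported_wheat_count == 463

    def test_duplicate_family_name_rejected(self, registry, tmp_path):
        doc = {"families": []}
        for entry in list(registry)[:2]:
            doc["families"].append({
                "name": "CEP", "peptide_class": entry.peptide_class,
                "description": entry.description,
                "mode_of_action": list(entry.mode_of_action),
                "reported_wheat_count": entry.reported_wheat_count,
                "motif": "none",
            })
        bad = tmp_path / "reg.yaml"
        bad.write_text(yaml.safe_dump(doc))
        with pytest.raises(RegistryValidationError, match="duplicate"):
            load_family_registry(bad, expected_families=2)

    def test_wrong_family_count_rejected(self, tmp_path):
        doc = {"families": [{
            "name": "CEP", "peptide_class": "PTM", "description": "x",
            "mode_of_action": ["Signal"], "reported_wheat_count": 1,
            "motif": "none",
        }]}
        bad = tmp_path / "reg.yaml"
        bad.write_text(yaml.safe_dump(doc))
        with pytest.raises(RegistryValidationError, match="expected 38"):
            load_family_registry(bad)

    def test_missing_field_rejected(self, tmp_path):
        doc = {"families": [{"name": "CEP", "peptide_class": "PTM"}]}
        bad = tmp_path / "reg.yaml"
        bad.write_text(yaml.safe_dump(doc))
        with pytest.raises(RegistryValidationError, match="missing fields"):
            load_family_registry(bad, expected_families=1)


class TestRegistrySummary:
    def test_total_gene_count(self, registry):
        assert registry_summary(registry).total == 1790

    def test_integer_class_shares(self, registry):
        shares = registry_summary(registry).per_class_shares
        # hand sums over the registry: PTM 198, CRP 1243, non-Cys 258, FP 91
        assert shares == {"PTM": 11, "CRP": 69, "NonCysNonPTM": 14,
                          "FunctionalPrecursor": 5}

    def test_class_shares_sum_to_100_within_rounding(self, registry):
        assert abs(sum(registry_summary(registry).per_class_shares.values()) - 100) <= 1

    def test_function_counts_aggregate_modes(self, registry):
        summary = registry_summary(registry)
        # Signal-mode rows of the registry sum to 1325 genes in 24 families
        assert summary.per_function_counts["Signal"] == 1325
        assert summary.per_function_families["Signal"] == 24


class TestCepPipDisambiguation:
    @pytest.mark.parametrize("cterm,expected", CEP_PIP_ORACLE)
    def test_against_hand_oracle(self, cterm, expected):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert disambiguate_cep_pip(cterm) == expected

    def test_non_proline_single_spacer_warns(self):
        with pytest.warns(UserWarning, match="proline"):
            assert disambiguate_cep_pip("DDRSGPSAGTGH") == "CEP"


class TestClassifyFamily:
    def test_planted_families_recovered_without_cross_assignment(
        self, registry, config
    ):
        proteome = generate_proteome(seed=23, registry=registry, config=config)
        planted = [(g, t) for g, t in proteome.truth.items()
                   if t.category == "planted_ssp"]
        by_gene = {r.gene_id: r for r in proteome.records}
        for gene, truth in planted:
            assignment = classify_family(
                by_gene[gene], proteome.sp_calls[gene], registry, config
            )
            assert assignment.family == truth.family
            assert assignment.match_span == truth.domain_span

    def test_random_mature_is_unclassified(self, registry, config):
        call = SignalPeptideCall(True, cleavage_after=17, score=1.0)
        seq = "MK" + "L" * 8 + "NQDE" + "ATA" + "DDENNQQKKRRHHEENNQQDDEE" * 3
        assignment = classify_family(seq, call, registry, config)
        assert assignment.family == "unclassified"
        assert assignment.match_span is None

    def test_order_independence(self, registry, config):
        proteome = generate_proteome(seed=29, registry=registry, config=config)
        planted = [r for r in proteome.records
                   if proteome.truth[r.gene_id].category == "planted_ssp"]
        forward = [classify_family(r, proteome.sp_calls[r.gene_id], registry, config)
                   for r in planted]
        backward = [classify_family(r, proteome.sp_calls[r.gene_id], registry, config)
                    for r in reversed(planted)]
        assert forward == list(reversed(backward))

    def test_cep_planted_resolves_via_spacer_rule(self, registry, config):
        proteome = generate_proteome(
            family_mix=["CEP", "PIP"], seed=31, registry=registry, config=config
        )
        for gene, truth in proteome.truth.items():
            if truth.category != "planted_ssp":
                continue
            rec = next(r for r in proteome.records if r.gene_id == gene)
            assignment = classify_family(rec, proteome.sp_calls[gene], registry, config)
            assert assignment.family == truth.family


class TestCysteineProfile:
    @pytest.mark.parametrize("n_cys,expected", [(4, True), (3, False),
                                                (18, False), (0, False), (16, True)])
    def test_even_2_to_16_rule(self, n_cys, expected, config):
        mature = "QQNN" + "C" * n_cys + "EEDD"
        assert cysteine_profile(mature).is_crp(config) is expected

    def test_counts_whole_mature_sequence(self):
        profile = cysteine_profile("CQQQQQQQQQC")
        assert profile.cys_count == 2 and profile.mature_length == 11

    def test_spectrum_hand_counts(self, config):
        profiles = [CysteineProfile(50, n) for n in (2, 4, 6, 14)]
        histogram, share = crp_spectrum(profiles, config)
        assert histogram == {2: 1, 4: 1, 6: 1, 14: 1}
        assert share == pytest.approx(75.0)

    def test_spectrum_all_low(self, config):
        _, share = crp_spectrum([CysteineProfile(50, 2)] * 3, config)
        assert share == pytest.approx(100.0)

    def test_spectrum_empty_is_absent(self, config):
        histogram, share = crp_spectrum([CysteineProfile(50, 3)], config)
        assert histogram == {} and share is None
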