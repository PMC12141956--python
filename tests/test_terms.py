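"""Term verification semantics and accuracy-report aggregation."""

from __future__ import annotations

import io

import pytest

from assocverify.associations import AssociationPair, ConfigurationError
from assocverify.ontology import load_obo, normalize_label
from assocverify.terms import (
    TermVerdict,
    VerificationStatus,
    accuracy_report,
    round_half_up,
    verify_association_terms,
    verify_term,
)

SYMP_BLISTER_OBO = "[Term]\nid: SYMP:0000184\nname: blister\n"


def brute_force_verify(term_text, ontology):
    """Independent oracle: scan every (term, name/synonym) string pair."""
    key = normalize_label(term_text)
    name_ids, synonym_ids = set(), set()
    if key:
        for term in ontology.terms_by_id.values():
            if term.obsolete:
                continue
            if normalize_label(term.name) == key:
                name_ids.add(term.id)
            elif any(normalize_label(s.text) == key for s in term.synonyms):
                synonym_ids.add(term.id)
    if name_ids:
        status = VerificationStatus.VERIFIED_NAME
    elif synonym_ids:
        status = VerificationStatus.VERIFIED_SYNONYM
    else:
        status = VerificationStatus.UNVERIFIED
    return status, name_ids, synonym_ids


class TestVerifyTerm:
    def test_hypertension_by_name(self, doid_fixture):
        verdict = verify_term("hypertension", doid_fixture)
        assert verdict.status is VerificationStatus.VERIFIED_NAME
        assert verdict.matched_ids == {"DOID:10763"}

    @pytest.mark.parametrize("label", ["HTN", "vascular hypertensive disorder"])
    def test_hypertension_by_synonym(self, doid_fixture, label):
        verdict = verify_term(label, doid_fixture)
        assert verdict.status is VerificationStatus.VERIFIED_SYNONYM
        assert verdict.matched_ids == {"DOID:10763"}

    def test_lay_paraphrase_is_unverified(self):
        symp = load_obo(io.StringIO(SYMP_BLISTER_OBO), "SYMP")
        verdict = verify_term("itchy blisters", symp)
        assert verdict.status is VerificationStatus.UNVERIFIED
        assert verdict.matched_ids == set()

    def test_unverified_iff_no_matched_ids(self, doid_fixture):
        for label in ("hypertension", "HTN", "no such disease"):
            verdict = verify_term(label, doid_fixture)
            assert (verdict.status is VerificationStatus.UNVERIFIED) == (
                not verdict.matched_ids
            )

    def test_agrees_with_brute_force_scan(self, tiny_suite):
        ontology = tiny_suite.source_ontology
        probes = [t.name for t in ontology.terms_by_id.values()]
        probes += [
            s.text for t in ontology.terms_by_id.values() for s in t.synonyms
        ]
        probes += [p.source_label for p in tiny_suite.pairs]
        probes += ["", "unrelated words entirely"]
        for probe in probes:
            verdict = verify_term(probe, ontology)
            status, name_ids, synonym_ids = brute_force_verify(probe, ontology)
            assert verdict.status is status, probe
            assert verdict.name_ids == name_ids
            assert verdict.synonym_ids == synonym_ids


class TestVerifyAssociationTerms:
    def test_order_preserved_and_both_endpoints(self, small_suite):
        results = verify_association_terms(
            small_suite.pairs, small_suite.source_ontology, small_suite.target_ontology
        )
        assert [p for p, _, _ in results] == small_suite.pairs

    def test_planted_validity_recovered_exactly(self, small_suite):
        results = verify_association_terms(
            small_suite.pairs, small_suite.source_ontology, small_suite.target_ontology
        )
        for (_, sv, tv), plant in zip(results, small_suite.plant_log.pairs):
            assert sv.verified == plant.source_valid
            assert tv.verified == plant.target_valid

    def test_prefix_mismatch_is_configuration_error(self, doid_fixture):
        pair = AssociationPair("GO:0006915", "x", "SYMP:1", "y", "disease_symptom")
        with pytest.raises(ConfigurationError):
            verify_association_terms([pair], doid_fixture, doid_fixture)

    def test_empty_pair_list(self, doid_fixture):
        assert verify_association_terms([], doid_fixture, doid_fixture) == []


def _verdict(status):
    ids = frozenset({"DOID:1"}) if status != VerificationStatus.UNVERIFIED else frozenset()
    return TermVerdict(
        term_text="t",
        status=status,
        name_ids=ids if status is VerificationStatus.VERIFIED_NAME else frozenset(),
        synonym_ids=ids if status is VerificationStatus.VERIFIED_SYNONYM else frozenset(),
    )


class TestAccuracyReport:
    def test_nine_of_ten(self):
        verdicts = [_verdict(VerificationStatus.VERIFIED_NAME)] * 9 + [
            _verdict(VerificationStatus.UNVERIFIED)
        ]
        assert round_half_up(accuracy_report(verdicts).combined_pct) == 90.00

    def test_mixed_counts(self):
        verdicts = (
            [_verdict(VerificationStatus.VERIFIED_NAME)] * 2
            + [_verdict(VerificationStatus.VERIFIED_SYNONYM)]
            + [_verdict(VerificationStatus.UNVERIFIED)]
        )
        report = accuracy_report(verdicts)
        assert report.combined_pct == 75.0
        assert report.name_pct == 50.0
        assert report.synonym_pct == 25.0

    def test_combined_counts_all_non_unverified(self, small_suite):
        results = verify_association_terms(
            small_suite.pairs, small_suite.source_ontology, small_suite.target_ontology
        )
        verdicts = [sv for _, sv, _ in results]
        report = accuracy_report(verdicts)
        n_unverified = sum(1 for v in verdicts if not v.verified)
        assert report.combined_pct == 100.0 * (len(verdicts) - n_unverified) / len(verdicts)
        assert report.combined_pct >= report.name_pct
        assert report.combined_pct >= report.synonym_pct

    def test_synonym_rate_counts_name_matches_with_synonym_evidence(self):
        verdicts = [
            TermVerdict(
                term_text="t",
                status=VerificationStatus.VERIFIED_NAME,
                name_ids=frozenset({"DOID:1"}),
                synonym_ids=frozenset({"DOID:2"}),
            ),
            _verdict(VerificationStatus.UNVERIFIED),
        ]
        report = accuracy_report(verdicts)
        assert report.name_pct == 50.0
        assert report.synonym_pct == 50.0
        assert report.combined_pct == 50.0

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            accuracy_report([])

    def test_display_rounding_is_half_up(self):
        assert round_half_up(93.365) == 93.37
        assert round_half_up(0.005) == 0.01
        assert round_half_up(85.714285) == 85.71
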