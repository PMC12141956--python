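"""Co-occurrence counting, period stratification, and coverage reports."""

from __future__ import annotations

import io
import textwrap

import pytest

from assocverify.associations import AssociationPair, ConfigurationError
from assocverify.coverage import (
    AbstractRecord,
    Corpus,
    PairCoverage,
    assign_period,
    consistency_report,
    contains_label,
    count_cooccurrence,
    coverage_report,
    read_corpus_jsonl,
    read_corpus_medline,
    split_by_period,
    verify_associations,
)
from assocverify.fixtures import gen_planted_setup
from assocverify.ontology import load_obo, normalize_label
from assocverify.terms import round_half_up


def pair(src="X", tgt="Y", assoc_type="disease_symptom"):
    return AssociationPair("DOID:1", src, "SYMP:2", tgt, assoc_type)


def corpus(*texts, label="c"):
    return Corpus(
        label=label,
        records=[AbstractRecord(f"A{i}", 2020, t) for i, t in enumerate(texts)],
    )


def naive_count(p, corp):
    """Oracle: normalize then boundary-constrained substring scan per abstract."""
    n = 0
    for record in corp.records:
        text = f" {normalize_label(record.text)} "
        if (
            f" {normalize_label(p.source_label)} " in text
            and f" {normalize_label(p.target_label)} " in text
        ):
            n += 1
    return n


class TestAssignPeriod:
    @pytest.mark.parametrize(
        ("year", "period"),
        [(2009, "P1"), (2014, "P1"), (2015, "P2"), (2019, "P2"),
         (2020, "P3"), (2024, "P3"), (2008, None), (2025, None), (None, None)],
    )
    def test_five_year_buckets(self, year, period):
        assert assign_period(year) == period


class TestCountCooccurrence:
    def test_direct_count(self):
        corp = corpus("X and Y", "only X", "Y then X")
        assert count_cooccurrence(pair(), corp) == 2

    def test_whole_token_matching_rejects_morphological_variants(self):
        corp = corpus("patients presented rashes and fever")
        assert count_cooccurrence(pair("rash", "fever"), corp) == 0
        corp2 = corpus("patients presented rash and fever")
        assert count_cooccurrence(pair("rash", "fever"), corp2) == 1

    def test_multi_word_labels_must_be_contiguous(self):
        corp = corpus("breast tissue and lung cancer studied")
        assert count_cooccurrence(pair("breast cancer", "lung"), corp) == 0

    def test_punctuation_and_case_insensitive(self):
        corp = corpus("Bull's-Eye rash was seen; FEVER too.")
        assert count_cooccurrence(pair("bulls eye rash", "fever"), corp) == 0
        assert count_cooccurrence(pair("bull s eye rash", "fever"), corp) == 1

    def test_repeat_mentions_count_once_per_abstract(self):
        corp = corpus("X and Y and X and Y and Y")
        assert count_cooccurrence(pair(), corp) == 1

    def test_symmetry_under_endpoint_swap(self, tiny_suite):
        for p in tiny_suite.pairs[:20]:
            swapped = AssociationPair(
                p.target_id, p.target_label, p.source_id, p.source_label, p.assoc_type
            )
            assert count_cooccurrence(p, tiny_suite.corpus) == count_cooccurrence(
                swapped, tiny_suite.corpus
            )

    def test_monotone_in_corpus_growth(self, tiny_suite):
        half = Corpus("half", tiny_suite.corpus.records[: len(tiny_suite.corpus) // 2])
        for p in tiny_suite.pairs[:20]:
            assert count_cooccurrence(p, half) <= count_cooccurrence(p, tiny_suite.corpus)

    def test_planted_counts_recovered_exactly(self, tiny_suite):
        coverages = verify_associations(tiny_suite.pairs, tiny_suite.corpus)
        for cov, plant in zip(coverages, tiny_suite.plant_log.pairs):
            assert cov.counter == len(plant.planted_abstract_ids)

    def test_agrees_with_naive_scan_oracle(self, tiny_suite):
        assert len(tiny_suite.corpus) <= 100
        coverages = verify_associations(tiny_suite.pairs, tiny_suite.corpus)
        for cov, p in zip(coverages, tiny_suite.pairs):
            assert cov.counter == naive_count(p, tiny_suite.corpus)


class TestSynonymExpansion:
    def test_synonym_mention_counts_only_with_expansion(self, doid_fixture):
        symp = load_obo(io.StringIO("[Term]\nid: SYMP:1\nname: headache\n"), "SYMP")
        p = AssociationPair("DOID:10763", "hypertension", "SYMP:1", "headache",
                            "disease_symptom")
        corp = corpus("HTN with severe headache reported")
        assert count_cooccurrence(p, corp) == 0
        assert count_cooccurrence(p, corp, synonym_expansion=(doid_fixture, symp)) == 1


class TestVerifyAssociations:
    def test_zero_counter_pairs_are_kept_and_flagged(self):
        corp = corpus("X and Y here")
        pairs = [pair(), pair("absent", "labels")]
        coverages = verify_associations(pairs, corp)
        assert [c.verified for c in coverages] == [True, False]
        assert coverages[1].counter == 0

    def test_all_absent_means_all_unverified(self, tiny_suite):
        empty_ish = corpus("nothing relevant at all")
        coverages = verify_associations(tiny_suite.pairs, empty_ish)
        assert all(not c.verified for c in coverages)


class TestCoverageReport:
    def test_six_of_seven_split(self):
        coverages = [
            PairCoverage(pair(), counter=c) for c in [1, 2, 3, 1, 1, 4, 0]
        ]
        (row,) = coverage_report({("disease_drug", "P1"): coverages})
        assert round_half_up(row.verified_pct) == 85.71
        assert round_half_up(row.unverified_pct) == 14.29
        assert row.verified_pct + row.unverified_pct == 100.0

    def test_avg_frequency_over_verified_only(self):
        coverages = [PairCoverage(pair(), counter=c) for c in (3, 1, 0, 0)]
        (row,) = coverage_report({("disease_symptom", "all"): coverages})
        assert row.avg_frequency == 2.0

    def test_no_verified_pairs_gives_none(self):
        coverages = [PairCoverage(pair(), counter=0)]
        (row,) = coverage_report({("disease_symptom", "all"): coverages})
        assert row.avg_frequency is None
        assert row.verified_pct == 0.0

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            coverage_report({("disease_drug", "P1"): []})


class TestConsistencyReport:
    def test_counts_and_percentages(self):
        pairs, corp = gen_planted_setup(7, 6, "disease_drug", seed=3)
        rows = consistency_report({"disease_drug": pairs}, {"m1": corp})
        (row,) = rows
        assert (row.count, row.total) == (6, 7)
        assert round_half_up(row.percentage) == 85.71

    def test_zero_hits(self):
        pairs, corp = gen_planted_setup(10, 0, "disease_gene", seed=3)
        (row,) = consistency_report({"disease_gene": pairs}, {"m": corp})
        assert row.count == 0 and row.percentage == 0.0

    def test_missing_corpus_is_configuration_error(self):
        pairs, corp = gen_planted_setup(3, 1, "disease_drug", seed=3)
        with pytest.raises(ConfigurationError):
            consistency_report({"disease_drug": pairs}, {"m": corp}, models=["m", "m2"])


class TestCorpusIO:
    def test_split_by_period_excludes_yearless(self):
        corp = Corpus(
            "c",
            [
                AbstractRecord("a", 2010, "t"),
                AbstractRecord("b", None, "t"),
                AbstractRecord("c", 1999, "t"),
                AbstractRecord("d", 2021, "t"),
            ],
        )
        sub, excluded = split_by_period(corp)
        assert excluded == 2
        assert [r.record_id for r in sub["P1"].records] == ["a"]
        assert [r.record_id for r in sub["P3"].records] == ["d"]

    def test_duplicate_record_ids_rejected(self):
        with pytest.raises(ValueError):
            Corpus("c", [AbstractRecord("a", 2010, "x"), AbstractRecord("a", 2011, "y")])

    def test_jsonl_reader_concatenates_title_and_abstract(self, tmp_path):
        path = tmp_path / "c.jsonl"
        path.write_text(
            '{"id": "1", "year": 2012, "title": "About X", "abstract": "and Y."}\n'
            '{"id": "2", "year": null, "title": "t", "abstract": "body"}\n'
        )
        corp = read_corpus_jsonl(path)
        assert len(corp) == 2
        assert contains_label(corp.records[0].text, "X")
        assert contains_label(corp.records[0].text, "Y")
        assert corp.records[1].year is None

    def test_medline_reader(self, tmp_path):
        text = textwrap.dedent(
            """\
            PMID- 12345
            DP  - 2016 Mar
            TI  - Hypertension and headache in a cohort.
            AB  - We observed HTN frequently.

            PMID- 67890
            DP  - 2021
            TI  - Another study.
            AB  - Nothing here.
            """
        )
        path = tmp_path / "corpus.txt"
        path.write_text(text)
        corp = read_corpus_medline(path)
        assert [r.record_id for r in corp.records] == ["12345", "67890"]
        assert corp.records[0].year == 2016
        assert contains_label(corp.records[0].text, "hypertension")
        assert contains_label(corp.records[0].text, "HTN")
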