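"""Codeset adaptation, discrepancy classification, and audit reports."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snomedcci._util import normalize_code
from snomedcci.codesets import Codeset
from snomedcci.crosswalk import (
    Adjudication,
    DiscrepancyRecord,
    adapt_codeset,
    audit_shares,
    classify_discrepancy,
    diagnostics_table,
    find_discrepant_codes,
    read_adjudication,
    write_adjudication,
)
from snomedcci.errors import ContractError
from snomedcci.vocab import ICD10CM, SNOMED, Concept, VocabularyStore

from conftest import adapt_all


class TestPartition:
    def test_identical_inputs_no_discrepancies(self):
        p = find_discrepant_codes({"A", "B"}, {"a", "B"})
        assert p.snomed_only == frozenset() and p.quan_only == frozenset()
        assert p.both == {"A", "B"}

    def test_set_algebra(self):
        p = find_discrepant_codes({"a", "b"}, {"b", "c"})
        assert p.both == {"B"}
        assert p.quan_only == {"A"}
        assert p.snomed_only == {"C"}

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(q=st.sets(st.text(alphabet="ABCDE12", min_size=1, max_size=3)),
           b=st.sets(st.text(alphabet="ABCDE12", min_size=1, max_size=3)))
    def test_partition_completeness(self, q, b):
        p = find_discrepant_codes(q, b)
        norm = {normalize_code(c) for c in q} | {normalize_code(c) for c in b}
        assert p.union_size == len(norm)
        assert p.both | p.snomed_only | p.quan_only == norm


class TestClassifier:
    def test_snomed_only_is_fanout(self, tiny_store):
        cat = classify_discrepancy(tiny_store, "snomed_only", "A01.2", ICD10CM,
                                   frozenset({"A011"}))
        assert cat == "multiple_icd_to_one_snomed"

    def test_quan_only_without_edges_is_deprecated(self, tiny_store):
        cat = classify_discrepancy(tiny_store, "quan_only", "A09.9", ICD10CM,
                                   frozenset({"A099"}))
        assert cat == "deprecated_unmapped"

    def test_quan_only_with_edges_is_specificity(self, tiny_store):
        cat = classify_discrepancy(tiny_store, "quan_only", "A01.1", ICD10CM,
                                   frozenset({"A011"}))
        assert cat == "specificity"

    def test_non_discrepant_input_rejected(self, tiny_store):
        with pytest.raises(ContractError):
            classify_discrepancy(tiny_store, "snomed_only", "A01.1", ICD10CM,
                                 frozenset({"A011"}))

    def test_record_invariants_enforced(self):
        with pytest.raises(ContractError):
            DiscrepancyRecord("chf", "X", ICD10CM, "snomed_only", "deprecated_unmapped")
        with pytest.raises(ContractError):
            DiscrepancyRecord("chf", "X", ICD10CM, "quan_only", "specificity",
                              adjudication="information_gain")


def _perfect_store():
    concepts = [
        Concept(1, "B01.1", ICD10CM), Concept(2, "B02.2", ICD10CM),
        Concept(10, "900010", SNOMED), Concept(11, "900011", SNOMED),
    ]
    return VocabularyStore.from_concepts(concepts, [(1, 10), (2, 11)])


class TestAdaptation:
    def test_perfect_crosswalk_empty_ledger(self):
        store = _perfect_store()
        cs = Codeset(name="chf", vocabulary=ICD10CM, codes={"B01.1", "B02.2"})
        res = adapt_codeset(store, cs)
        assert res.ledger == []
        assert len(res.snomed_codeset) == 2

    def test_empty_codeset_rejected(self):
        store = _perfect_store()
        with pytest.raises(ContractError):
            adapt_codeset(store, Codeset(name="chf", vocabulary=ICD10CM))

    def test_adjudication_unknown_concept_rejected(self):
        store = _perfect_store()
        cs = Codeset(name="chf", vocabulary=ICD10CM, codes={"B01.1"})
        adj = Adjudication()
        adj.add(999999, "exclude")
        with pytest.raises(ContractError, match="999999"):
            adapt_codeset(store, cs, adj)

    def test_fanout_noise_keeps_concept_and_ledgers_extras(self, worked_examples_vocab):
        """Diabetic-kidney fan-out: secondary/drug-induced codes are ledgered
        as added noise while the shared concept stays in the set."""
        sv = worked_examples_vocab
        sets = [cs for (c, _), cs in sorted(sv.quan_codesets.items())
                if c == "diabetes_with_cc"]
        res = adapt_codeset(sv.store, sets, sv.adjudication)
        assert "192279" in res.snomed_codeset.codes
        noise = {r.code for r in res.ledger if r.adjudication == "added_noise"}
        assert noise == {"249.4", "E09.2"}

    def test_information_gain_example(self, worked_examples_vocab):
        sv = worked_examples_vocab
        res = adapt_codeset(sv.store, sv.quan_codesets[("cvd", ICD10CM)],
                            sv.adjudication)
        assert "443454" in res.snomed_codeset.codes
        (rec,) = res.ledger
        assert (rec.code, rec.category, rec.adjudication) == (
            "G43.61", "multiple_icd_to_one_snomed", "information_gain")

    def test_specificity_trap_excludes_concept(self, worked_examples_vocab):
        """I13.2-style: the over-broad concept is excluded, the in-set code is
        lost and ledgered as a specificity discrepancy."""
        sv = worked_examples_vocab
        res = adapt_codeset(sv.store, sv.quan_codesets[("chf", ICD10CM)],
                            sv.adjudication)
        assert res.snomed_codeset.codes == set()
        (rec,) = res.ledger
        assert (rec.code, rec.side, rec.category) == ("I13.2", "quan_only", "specificity")
        assert rec.adjudication is None

    def test_ground_truth_recovery_is_complete(self, small_vocab):
        """The classifier recovers every generator label exactly once."""
        _, ledgers, _ = adapt_all(small_vocab)
        got = {}
        for recs in ledgers.values():
            for r in recs:
                key = (r.condition, normalize_code(r.code), r.vocabulary)
                assert key not in got, "discrepant code ledgered twice"
                got[key] = (r.side, r.category, r.adjudication)
        assert len(got) == len(small_vocab.labels)
        for lab in small_vocab.labels:
            side, cat, adj = got[(lab.condition, normalize_code(lab.code), lab.vocabulary)]
            assert (side, cat) == (lab.side, lab.category)
            if cat == "multiple_icd_to_one_snomed":
                assert adj == lab.adjudication

    def test_snomed_sets_match_generator_expectation(self, small_vocab):
        snomed_sets, _, _ = adapt_all(small_vocab)
        for cond, cs in snomed_sets.items():
            assert cs.codes == small_vocab.expected_snomed[cond]


class TestReports:
    def test_empty_ledgers_all_zero(self):
        df = diagnostics_table({})
        total = df[df["condition"] == "total"].iloc[0]
        assert int(total["total"]) == 0

    def test_report_totals_equal_ledger_cardinality(self, small_vocab):
        _, ledgers, _ = adapt_all(small_vocab)
        df = diagnostics_table(ledgers)
        n_records = sum(len(v) for v in ledgers.values())
        assert int(df.loc[df["condition"] == "total", "total"].iloc[0]) == n_records

    def test_audit_shares_conserve(self, small_vocab):
        _, ledgers, partitions = adapt_all(small_vocab)
        from snomedcci.crosswalk import code_overlap_table

        shares = audit_shares(code_overlap_table(partitions),
                              diagnostics_table(ledgers))
        assert shares["n_discrepant"] == sum(len(v) for v in ledgers.values())
        assert shares["consistent_share_pct"] + shares["discrepant_share_pct"] == \
            pytest.approx(100.0, abs=0.1)


def test_adjudication_file_roundtrip(tmp_path):
    adj = Adjudication()
    adj.add(123, "exclude")
    adj.add("I13.2", "information_gain")
    p = tmp_path / "adj.csv"
    write_adjudication(adj, p)
    back = read_adjudication(p)
    assert back.by_snomed_id == {123: "exclude"}
    assert back.decision_for_code("i132") == "information_gain"
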