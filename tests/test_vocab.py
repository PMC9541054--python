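"""Vocabulary store: loading, forward/reverse mapping, hierarchy queries."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snomedcci.errors import ConceptLookupError, IntegrityError, SchemaError
from snomedcci.vocab import (
    ICD10CM,
    SNOMED,
    Concept,
    VocabularyStore,
    forward_map,
    load_vocabulary,
    reverse_map,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoading:
    def test_compact_dialect_roundtrip(self, tmp_path):
        c = _write(tmp_path, "concept.csv",
                   "concept_id,code,vocabulary,name,valid\n"
                   "1,I13.2,ICD10CM,hhckd,1\n"
                   "2,I13.1,ICD10CM,hhckd2,1\n"
                   "3,500100,SNOMED,target,1\n")
        r = _write(tmp_path, "rel.csv",
                   "source_concept_id,target_concept_id\n1,3\n")
        a = _write(tmp_path, "anc.csv",
                   "ancestor_concept_id,descendant_concept_id,min_levels\n")
        store = load_vocabulary(c, r, a, dialect="compact")
        assert store.n_concepts() == 3
        res = forward_map(store, {("I13.2", ICD10CM)})
        assert res.snomed_ids == {3}

    def test_omop_dialect_filters_non_maps_to(self, tmp_path):
        c = _write(tmp_path, "CONCEPT.tsv",
                   "concept_id\tconcept_code\tvocabulary_id\tconcept_name\tinvalid_reason\n"
                   "1\tI13.2\tICD10CM\tx\t\n"
                   "2\t500100\tSNOMED\ty\t\n"
                   "3\tB99\tICD10CM\tgone\tD\n")
        r = _write(tmp_path, "REL.tsv",
                   "concept_id_1\tconcept_id_2\trelationship_id\n"
                   "1\t2\tMaps to\n"
                   "1\t2\tIs a\n")
        store = load_vocabulary(c, r, None, dialect="omop")
        assert store.maps_to == {1: {2}}
        assert not store.concepts[3].valid

    def test_empty_relationship_file_gives_empty_queries(self, tmp_path):
        c = _write(tmp_path, "c.csv",
                   "concept_id,code,vocabulary,name,valid\n1,A01,ICD10CM,a,1\n")
        r = _write(tmp_path, "r.csv", "source_concept_id,target_concept_id\n")
        store = load_vocabulary(c, r, None, dialect="compact")
        res = forward_map(store, {("A01", ICD10CM)})
        assert res.snomed_ids == set()
        assert res.unmapped == [("A01", ICD10CM)]

    def test_missing_column_names_it(self, tmp_path):
        c = _write(tmp_path, "c.csv", "concept_id,code,name,valid\n")
        r = _write(tmp_path, "r.csv", "source_concept_id,target_concept_id\n")
        with pytest.raises(SchemaError, match="vocabulary"):
            load_vocabulary(c, r, None, dialect="compact")

    def test_dangling_edge_names_offender(self, tmp_path):
        c = _write(tmp_path, "c.csv",
                   "concept_id,code,vocabulary,name,valid\n1,A01,ICD10CM,a,1\n")
        r = _write(tmp_path, "r.csv", "source_concept_id,target_concept_id\n1,999\n")
        with pytest.raises(IntegrityError, match="999"):
            load_vocabulary(c, r, None, dialect="compact")


class TestMappingQueries:
    def test_forward_empty(self, tiny_store):
        assert forward_map(tiny_store, set()).snomed_ids == set()

    def test_forward_two_codes_one_target(self, tiny_store):
        res = forward_map(tiny_store, {("A01.1", ICD10CM), ("A01.2", ICD10CM)})
        assert res.snomed_ids == {10}
        assert res.unmapped == []

    def test_forward_normalizes_dots_and_case(self, tiny_store):
        res = forward_map(tiny_store, {("a011", ICD10CM)})
        assert res.snomed_ids == {10}

    def test_deprecated_code_reported_unmapped(self, tiny_store):
        res = forward_map(tiny_store, {("A09.9", ICD10CM)})
        assert res.snomed_ids == set()
        assert res.unmapped == [("A09.9", ICD10CM)]

    def test_reverse_shared_target_returns_both_sources(self, tiny_store):
        assert reverse_map(tiny_store, {10}, include_descendants=False) == {
            ("A01.1", ICD10CM), ("A01.2", ICD10CM)
        }

    def test_reverse_with_descendants_adds_child_sources(self, tiny_store):
        assert reverse_map(tiny_store, {10}, include_descendants=True) == {
            ("A01.1", ICD10CM), ("A01.2", ICD10CM), ("A02.1", ICD10CM)
        }

    def test_reverse_unknown_id_raises(self, tiny_store):
        with pytest.raises(ConceptLookupError, match="424242"):
            reverse_map(tiny_store, {424242})

    def test_roundtrip_containment(self, tiny_store):
        res = forward_map(tiny_store, {("A01.1", ICD10CM)})
        back = reverse_map(tiny_store, res.snomed_ids)
        assert ("A01.1", ICD10CM) in back


# -- property tests over random mapping graphs ----------------------------

@st.composite
def random_store(draw):
    n_icd = draw(st.integers(1, 20))
    n_sno = draw(st.integers(1, 15))
    concepts = [Concept(i, f"A{i:03d}", ICD10CM) for i in range(1, n_icd + 1)]
    concepts += [Concept(100 + j, str(100 + j), SNOMED) for j in range(1, n_sno + 1)]
    edges = draw(st.sets(
        st.tuples(st.integers(1, n_icd), st.integers(101, 100 + n_sno)),
        max_size=40,
    ))
    ancestors = draw(st.sets(
        st.tuples(st.integers(101, 100 + n_sno), st.integers(101, 100 + n_sno)),
        max_size=10,
    ))
    store = VocabularyStore.from_concepts(concepts, edges, ancestors)
    return store, sorted(edges)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=random_store())
def test_roundtrip_property(data):
    """Any fully-mapped codeset is contained in the back-map of its forward map."""
    store, edges = data
    mapped_sources = {s for s, _ in edges}
    codes = {(store.concepts[s].code, ICD10CM) for s in mapped_sources}
    fwd = forward_map(store, codes)
    assert not fwd.unmapped
    back = reverse_map(store, fwd.snomed_ids, include_descendants=True)
    assert codes <= back


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=random_store(), subset_seed=st.integers(0, 1000))
def test_agrees_with_naive_edge_scan(data, subset_seed):
    """forward/reverse mapping agree with a brute-force scan over edge lists."""
    store, edges = data
    icd_ids = [i for i, c in store.concepts.items() if c.vocabulary == ICD10CM]
    chosen = [i for i in icd_ids if (i * 2654435761 + subset_seed) % 3 == 0]
    codes = {(store.concepts[i].code, ICD10CM) for i in chosen}

    fwd = forward_map(store, codes)
    naive_fwd = {t for s, t in edges if s in chosen}
    assert fwd.snomed_ids == naive_fwd

    back = reverse_map(store, naive_fwd, include_descendants=False)
    naive_back = {
        (store.concepts[s].code, ICD10CM) for s, t in edges if t in naive_fwd
    }
    assert back == naive_back


@settings(max_examples=40, deadline=None, derandomize=True)
@given(data=random_store(), extra=st.integers(101, 115))
def test_reverse_map_monotone(data, extra):
    """Adding a SNOMED id to the query never shrinks the result."""
    store, edges = data
    targets = {t for _, t in edges}
    if not targets or extra not in store.concepts:
        return
    base = set(list(targets)[:2])
    small = reverse_map(store, base)
    large = reverse_map(store, base | {extra})
    assert small <= large
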