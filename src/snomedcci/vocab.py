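"""Vocabulary snapshot store: concepts, maps-to edges, hierarchy.

Loads OMOP-vocabulary-shaped tables (CONCEPT, CONCEPT_RELATIONSHIP,
CONCEPT_ANCESTOR) or the toolkit's compact fixture dialect, and answers the
three queries the crosswalk needs:

* forward: source (ICD-9-CM / ICD-10-CM) codes -> SNOMED standard concepts,
  via "Maps to" edges;
* reverse: SNOMED concepts -> every source code mapping into them,
  optionally through the descendant closure of the input set;
* hierarchy: descendant closure of a set of SNOMED concepts.

Only the "Maps to" relationship is consumed; other relationship rows are
ignored on load. The ancestor table is stored with its reflexive closure
(every concept is its own descendant at zero levels), which the loader adds
if the snapshot omits it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import normalize_code
from .errors import ConceptLookupError, IntegrityError, SchemaError

logger = logging.getLogger(__name__)

SNOMED = "SNOMED"
ICD9CM = "ICD9CM"
ICD10CM = "ICD10CM"
KNOWN_VOCABULARIES = frozenset({SNOMED, ICD9CM, ICD10CM})

#: column spellings per dialect: {dialect: {table: {internal: file column}}}
_DIALECTS: Mapping[str, Mapping[str, Mapping[str, str]]] = {
    "omop": {
        "concept": {
            "concept_id": "concept_id",
            "code": "concept_code",
            "vocabulary": "vocabulary_id",
            "name": "concept_name",
            "invalid_reason": "invalid_reason",
        },
        "relationship": {
            "source_concept_id": "concept_id_1",
            "target_concept_id": "concept_id_2",
            "relationship_id": "relationship_id",
        },
        "ancestor": {
            "ancestor_concept_id": "ancestor_concept_id",
            "descendant_concept_id": "descendant_concept_id",
            "min_levels": "min_levels_of_separation",
        },
    },
    "compact": {
        "concept": {
            "concept_id": "concept_id",
            "code": "code",
            "vocabulary": "vocabulary",
            "name": "name",
            "valid": "valid",
        },
        "relationship": {
            "source_concept_id": "source_concept_id",
            "target_concept_id": "target_concept_id",
        },
        "ancestor": {
            "ancestor_concept_id": "ancestor_concept_id",
            "descendant_concept_id": "descendant_concept_id",
            "min_levels": "min_levels",
        },
    },
}

# OMOP vocabulary downloads are tab-delimited; the compact fixture dialect is CSV.
_SEP = {"omop": "\t", "compact": ","}


@dataclass(frozen=True)
class Concept:
    """One vocabulary entry.

    ``valid=False`` marks a code deprecated/invalid in this snapshot; such
    codes typically carry no maps-to edge.
    """

    concept_id: int
    code: str
    vocabulary: str
    name: str = ""
    valid: bool = True


@dataclass
class VocabularyStore:
    """Indexed vocabulary snapshot.

    Construct via :func:`load_vocabulary` or :meth:`from_concepts`. All edge
    endpoints are checked against the concept table; dangling endpoints raise
    :class:`IntegrityError` at construction.
    """

    concepts: dict[int, Concept]
    #: source concept id -> set of SNOMED target ids ("Maps to")
    maps_to: dict[int, set[int]] = field(default_factory=dict)
    #: SNOMED target id -> set of source concept ids (inverse of maps_to)
    maps_from: dict[int, set[int]] = field(default_factory=dict)
    #: ancestor id -> descendant ids, reflexive closure included
    descendants_of: dict[int, set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._by_code: dict[tuple[str, str], int] = {}
        for cid, c in self.concepts.items():
            key = (normalize_code(c.code), c.vocabulary)
            # valid concepts win the (code, vocabulary) slot over deprecated ones
            if key not in self._by_code or c.valid:
                self._by_code[key] = cid
        # reflexive closure is an invariant of the store
        for cid in self.concepts:
            self.descendants_of.setdefault(cid, set()).add(cid)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_concepts(
        cls,
        concepts: Iterable[Concept],
        maps_to: Iterable[tuple[int, int]] = (),
        ancestors: Iterable[tuple[int, int]] = (),
    ) -> "VocabularyStore":
        """Build a store from in-memory concepts and edge pairs.

        ``maps_to`` pairs are (source_id, target_id); ``ancestors`` pairs are
        (ancestor_id, descendant_id). Reflexive ancestor rows are implied.
        """
        cmap = {c.concept_id: c for c in concepts}
        store = cls(concepts=cmap)
        dangling: list[int] = []
        for src, tgt in maps_to:
            if src not in cmap:
                dangling.append(src)
            if tgt not in cmap:
                dangling.append(tgt)
            if src in cmap and tgt in cmap:
                store.maps_to.setdefault(src, set()).add(tgt)
                store.maps_from.setdefault(tgt, set()).add(src)
        for anc, desc in ancestors:
            if anc not in cmap:
                dangling.append(anc)
            if desc not in cmap:
                dangling.append(desc)
            if anc in cmap and desc in cmap:
                store.descendants_of.setdefault(anc, set()).add(desc)
        if dangling:
            raise IntegrityError("edges", dangling)
        return store

    # -- lookups -----------------------------------------------------------

    def concept_by_code(self, code: str, vocabulary: str) -> Concept | None:
        cid = self._by_code.get((normalize_code(code), vocabulary))
        return self.concepts.get(cid) if cid is not None else None

    def require_ids(self, ids: Iterable[int]) -> None:
        unknown = [i for i in ids if i not in self.concepts]
        if unknown:
            raise ConceptLookupError(unknown)

    def descendant_closure(self, snomed_ids: Iterable[int]) -> set[int]:
        """All descendants (including the inputs themselves) of ``snomed_ids``."""
        ids = list(snomed_ids)
        self.require_ids(ids)
        out: set[int] = set()
        for i in ids:
            out |= self.descendants_of.get(i, {i})
        return out

    def n_concepts(self) -> int:
        return len(self.concepts)


@dataclass
class ForwardMapResult:
    """Result of a forward (source -> SNOMED) mapping query.

    ``snomed_ids`` is the de-duplicated union of maps-to targets; ``unmapped``
    lists input codes with no maps-to edge (deprecated or unmappable codes are
    data, not errors).
    """

    snomed_ids: set[int]
    unmapped: list[tuple[str, str]]


def _read_table(path: str | Path, table: str, dialect: str) -> pd.DataFrame:
    colmap = _DIALECTS[dialect][table]
    df = pd.read_csv(path, sep=_SEP[dialect], dtype=str, keep_default_na=False)
    missing = set(colmap.values()) - set(df.columns)
    if missing:
        raise SchemaError(table, missing)
    df = df.rename(columns={v: k for k, v in colmap.items()})
    return df


def load_vocabulary(
    concept_path: str | Path,
    relationship_path: str | Path,
    ancestor_path: str | Path | None = None,
    dialect: str = "omop",
) -> VocabularyStore:
    """Load a vocabulary snapshot from delimited files.

    Parameters
    ----------
    concept_path, relationship_path, ancestor_path
        The concept, concept-relationship and (optional) concept-ancestor
        tables. Only ``Maps to`` relationship rows are consumed.
    dialect
        ``"omop"`` (tab-delimited, OMOP column names) or ``"compact"``
        (CSV, the toolkit's fixture dialect).

    Raises
    ------
    SchemaError
        if a required column is absent (the message names it).
    IntegrityError
        if an edge references a concept id not in the concept table.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")

    cdf = _read_table(concept_path, "concept", dialect)
    if dialect == "omop":
        valid = cdf["invalid_reason"].str.strip() == ""
    else:
        valid = cdf["valid"].str.strip().str.lower().isin({"1", "true", "t", "yes", ""})
    name_col = cdf["name"]
    concepts = [
        Concept(concept_id=int(cid), code=code, vocabulary=voc, name=nm, valid=bool(v))
        for cid, code, voc, nm, v in zip(
            cdf["concept_id"], cdf["code"], cdf["vocabulary"], name_col, valid
        )
    ]

    rdf = _read_table(relationship_path, "relationship", dialect)
    if dialect == "omop":
        rdf = rdf[rdf["relationship_id"].str.strip() == "Maps to"]
    edges = [
        (int(s), int(t))
        for s, t in zip(rdf["source_concept_id"], rdf["target_concept_id"])
    ]

    anc_pairs: list[tuple[int, int]] = []
    if ancestor_path is not None:
        adf = _read_table(ancestor_path, "ancestor", dialect)
        anc_pairs = [
            (int(a), int(d))
            for a, d in zip(adf["ancestor_concept_id"], adf["descendant_concept_id"])
        ]

    store = VocabularyStore.from_concepts(concepts, edges, anc_pairs)
    unknown_vocabs = {c.vocabulary for c in store.concepts.values()} - KNOWN_VOCABULARIES
    if unknown_vocabs:
        logger.warning("retaining concepts from unrecognized vocabularies: %s",
                       ", ".join(sorted(unknown_vocabs)))
    logger.info("loaded vocabulary: %d concepts, %d maps-to edges",
                len(store.concepts), sum(len(v) for v in store.maps_to.values()))
    return store


def forward_map(
    store: VocabularyStore, codes: Iterable[tuple[str, str]]
) -> ForwardMapResult:
    """Map source (code, vocabulary) pairs to the set of SNOMED target ids.

    Every maps-to target of every input code is included (a code with several
    targets contributes them all); codes with no edge land in ``unmapped``.
    """
    snomed_ids: set[int] = set()
    unmapped: list[tuple[str, str]] = []
    for code, vocab in sorted(set(codes)):
        concept = store.concept_by_code(code, vocab)
        targets = store.maps_to.get(concept.concept_id, set()) if concept else set()
        if targets:
            snomed_ids |= targets
        else:
            unmapped.append((code, vocab))
    return ForwardMapResult(snomed_ids=snomed_ids, unmapped=unmapped)


def reverse_map(
    store: VocabularyStore,
    snomed_ids: Iterable[int],
    include_descendants: bool = True,
) -> set[tuple[str, str]]:
    """All source (code, vocabulary) pairs whose maps-to target lies in
    ``snomed_ids`` — or, with ``include_descendants`` (the default, matching
    the usual codeset-expansion convention), in its descendant closure.

    Raises :class:`ConceptLookupError` for unknown ids.
    """
    ids = set(snomed_ids)
    store.require_ids(ids)
    targets = store.descendant_closure(ids) if include_descendants else ids
    out: set[tuple[str, str]] = set()
    for t in targets:
        for src in store.maps_from.get(t, ()):
            c = store.concepts[src]
            out.add((c.code, c.vocabulary))
    return out


def serialize_codes(codes: Iterable[tuple[str, str]]) -> list[tuple[str, str]]:
    """Deterministic (vocabulary, then code) ordering for report output."""
    return sorted(codes, key=lambda cv: (cv[1], cv[0]))
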