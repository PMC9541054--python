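from __future__ import annotations

import pytest

from snomedcci.codesets import CONDITION_ORDER
from snomedcci.crosswalk import adapt_codeset
from snomedcci.synth import (
    ClaimsSpec,
    default_vocab_spec,
    gen_claims,
    gen_vocabulary,
    small_vocab_spec,
)
from snomedcci.vocab import ICD10CM, SNOMED, Concept, VocabularyStore


@pytest.fixture()
def tiny_store() -> VocabularyStore:
    """Hand-built snapshot: two ICD-10-CM codes sharing one SNOMED target,
    a descendant concept targeted by a third code, and a deprecated code."""
    concepts = [
        Concept(1, "A01.1", ICD10CM, "code a"),
        Concept(2, "A01.2", ICD10CM, "code b"),
        Concept(3, "A02.1", ICD10CM, "code d"),
        Concept(4, "A09.9", ICD10CM, "deprecated", valid=False),
        Concept(10, "100010", SNOMED, "parent concept"),
        Concept(11, "100011", SNOMED, "child concept"),
    ]
    maps_to = [(1, 10), (2, 10), (3, 11)]
    ancestors = [(10, 11)]
    return VocabularyStore.from_concepts(concepts, maps_to, ancestors)


@pytest.fixture(scope="session")
def small_vocab():
    """Fast synthetic vocabulary with every discrepancy category."""
    return gen_vocabulary(small_vocab_spec(seed=7))


@pytest.fixture(scope="session")
def worked_examples_vocab():
    """Only the three replica worked examples (tiny, fully curated)."""
    from snomedcci.synth import VocabSpec

    return gen_vocabulary(VocabSpec(counts={}, include_worked_examples=True))


@pytest.fixture(scope="session")
def default_vocab():
    """Full-size synthetic vocabulary mirroring the published audit counts."""
    return gen_vocabulary(default_vocab_spec(seed=0))


def adapt_all(sv, include_descendants: bool = True):
    """Adapt every condition of a synthetic vocabulary; returns
    (snomed_codesets, ledgers, partitions)."""
    snomed_sets, ledgers, partitions = {}, {}, {}
    for cond in CONDITION_ORDER:
        sets = [cs for (c, _v), cs in sorted(sv.quan_codesets.items()) if c == cond]
        if not sets:
            continue
        res = adapt_codeset(sv.store, sets, sv.adjudication,
                            include_descendants=include_descendants)
        snomed_sets[cond] = res.snomed_codeset
        ledgers[cond] = res.ledger
        for vocab, part in res.partitions.items():
            partitions[(cond, vocab)] = part
    return snomed_sets, ledgers, partitions


@pytest.fixture(scope="session")
def small_claims(small_vocab):
    """500-patient claims bundle with zero discordance (exact recovery)."""
    spec = ClaimsSpec(
        n_patients=500, calendar_year=2018, snomed_only_rate=0.0,
        quan_only_rate=0.0, eligible_fraction=1.0, underage_fraction=0.0,
        seed=11,
    )
    return gen_claims(spec, small_vocab)
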