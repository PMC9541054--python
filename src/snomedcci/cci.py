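"""Charlson comorbidity detection and weighted-score computation.

A condition is flagged when at least one diagnosis in the lookback window —
index date minus 365 days through the index date, both ends included —
matches the condition's codeset in the vocabulary the chosen coding
algorithm reads (``quan_icd9`` -> ICD-9-CM codes, ``quan_icd10`` ->
ICD-10-CM, ``snomed`` -> SNOMED concept codes, optionally pre-expanded to
descendants). Diagnoses in vocabularies the algorithm cannot read are
skipped and counted, not rejected: mixed-vocabulary extracts are normal.

The score is the weighted sum of flagged conditions. With the severity
hierarchy applied (the default), a milder condition's weight is dropped when
its severe counterpart is flagged; flag reporting and scoring are
independently configurable because descriptive tables conventionally report
both severities even when the score counts one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date, timedelta
from typing import Iterable, Mapping

import pandas as pd

from ._util import normalize_code
from .codesets import CONDITION_ORDER, Codeset, ComorbidityDefinition
from .errors import ContractError
from .vocab import ICD9CM, ICD10CM, SNOMED, VocabularyStore

logger = logging.getLogger(__name__)

LOOKBACK_DAYS = 365

#: coding algorithm -> the vocabulary of the diagnosis records it reads
ALGORITHM_VOCABULARY: Mapping[str, str] = {
    "snomed": SNOMED,
    "quan_icd9": ICD9CM,
    "quan_icd10": ICD10CM,
}


@dataclass(frozen=True)
class CciResult:
    """Per-patient condition flags and weighted score for one algorithm."""

    person_id: int
    algorithm: str
    flags: tuple[bool, ...]  # aligned with CONDITION_ORDER
    score: int

    def flag(self, condition: str) -> bool:
        return self.flags[CONDITION_ORDER.index(condition)]

    def flags_dict(self) -> dict[str, bool]:
        return dict(zip(CONDITION_ORDER, self.flags))


def expand_snomed_codeset(store: VocabularyStore, codeset: Codeset) -> Codeset:
    """Descendant-expanded copy of a SNOMED codeset.

    Concept membership for the SNOMED algorithm includes descendants of the
    curated concepts; the expansion is materialized once so per-record
    matching stays a set lookup.
    """
    if codeset.vocabulary != SNOMED:
        raise ContractError("descendant expansion applies to SNOMED codesets only")
    ids = []
    for code in codeset.codes:
        c = store.concept_by_code(code, SNOMED)
        if c is not None:
            ids.append(c.concept_id)
    expanded = Codeset(name=codeset.name, vocabulary=SNOMED,
                       codes=set(codeset.codes), provenance=dict(codeset.provenance))
    for sid in sorted(store.descendant_closure(ids)):
        code = store.concepts[sid].code
        if code not in expanded.codes:
            expanded.add(code, provenance="descendant")
    return expanded


def detect_conditions(
    diagnoses: Iterable[tuple[str, str, date]],
    index_date: date,
    definitions: Mapping[str, ComorbidityDefinition],
    algorithm: str,
) -> dict[str, bool]:
    """Flags for the 17 conditions from one patient's diagnosis history.

    ``diagnoses`` are (code, vocabulary, date) records; only records in the
    algorithm's vocabulary and inside the closed lookback window count.
    """
    if algorithm not in ALGORITHM_VOCABULARY:
        raise ContractError(f"unknown algorithm {algorithm!r}")
    vocab = ALGORITHM_VOCABULARY[algorithm]
    window_start = index_date - timedelta(days=LOOKBACK_DAYS)

    skipped = 0
    in_window: list[str] = []
    for code, v, d in diagnoses:
        if v != vocab:
            skipped += 1
            continue
        if window_start <= d <= index_date:
            in_window.append(code)
    if skipped:
        logger.debug("detect_conditions: skipped %d records in other vocabularies", skipped)

    flags: dict[str, bool] = {}
    for cond in CONDITION_ORDER:
        cs = definitions[cond].codeset_for(vocab)
        flags[cond] = bool(cs) and any(cs.matches(c) for c in in_window)
    return flags


def apply_flag_hierarchy(flags: Mapping[str, bool]) -> dict[str, bool]:
    """Clear a milder condition's flag when its severe counterpart is set."""
    out = dict(flags)
    for mild, severe in (("diabetes_without_cc", "diabetes_with_cc"),
                         ("mild_liver", "severe_liver"),
                         ("malignancy", "metastatic_tumor")):
        if out.get(severe):
            out[mild] = False
    return out


def compute_cci(
    flags: Mapping[str, bool],
    definitions: Mapping[str, ComorbidityDefinition],
    apply_hierarchy: bool = True,
) -> int:
    """Weighted Charlson score from condition flags."""
    missing = set(CONDITION_ORDER) - set(flags)
    if missing:
        raise ContractError(f"flags incomplete; missing {sorted(missing)}")
    score = 0
    for cond in CONDITION_ORDER:
        if not flags[cond]:
            continue
        d = definitions[cond]
        if apply_hierarchy and d.superseded_by and flags.get(d.superseded_by):
            continue
        score += d.weight
    return score


def score_cohort(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    definitions: Mapping[str, ComorbidityDefinition],
    algorithm: str,
    apply_hierarchy: bool = True,
    hierarchy_on_flags: bool = False,
) -> list[CciResult]:
    """Score every cohort member under one coding algorithm (vectorized).

    Parameters
    ----------
    cohort
        Frame with ``person_id`` and ``index_date`` columns.
    diagnoses
        Frame with ``person_id``, ``code``, ``vocabulary``, ``date``.
    algorithm
        ``"snomed"``, ``"quan_icd9"`` or ``"quan_icd10"``.
    apply_hierarchy, hierarchy_on_flags
        Whether the severity hierarchy reduces the score and/or the reported
        flags (independent switches).
    """
    if algorithm not in ALGORITHM_VOCABULARY:
        raise ContractError(f"unknown algorithm {algorithm!r}")
    vocab = ALGORITHM_VOCABULARY[algorithm]

    if cohort.empty:
        return []

    idx = cohort[["person_id", "index_date"]].copy()
    idx["index_date"] = pd.to_datetime(idx["index_date"])

    dx = diagnoses[diagnoses["vocabulary"] == vocab]
    n_skipped = len(diagnoses) - len(dx)
    if n_skipped:
        logger.debug("score_cohort(%s): skipped %d records in other vocabularies",
                     algorithm, n_skipped)
    dx = dx.merge(idx, on="person_id", how="inner")
    if not dx.empty:
        d = pd.to_datetime(dx["date"])
        delta = (dx["index_date"] - d).dt.days
        dx = dx[(delta >= 0) & (delta <= LOOKBACK_DAYS)]

    norm = dx["code"].map(normalize_code) if not dx.empty else pd.Series(dtype=str)

    flagged: dict[str, set[int]] = {}
    for cond in CONDITION_ORDER:
        cs = definitions[cond].codeset_for(vocab)
        if cs is None or dx.empty:
            flagged[cond] = set()
            continue
        mask = norm.isin(cs.normalized_codes())
        for p in cs.prefixes:
            mask |= norm.str.startswith(p)
        flagged[cond] = set(dx.loc[mask, "person_id"])

    results: list[CciResult] = []
    for pid in cohort["person_id"]:
        flags = {cond: pid in flagged[cond] for cond in CONDITION_ORDER}
        score = compute_cci(flags, definitions, apply_hierarchy=apply_hierarchy)
        if hierarchy_on_flags:
            flags = apply_flag_hierarchy(flags)
        results.append(CciResult(
            person_id=pid, algorithm=algorithm,
            flags=tuple(flags[c] for c in CONDITION_ORDER), score=score,
        ))
    return results


def results_frame(results: Iterable[CciResult]) -> pd.DataFrame:
    """Tabular view: one row per person with flags and the score."""
    rows = []
    for r in results:
        row: dict[str, object] = {"person_id": r.person_id, "algorithm": r.algorithm}
        row.update(r.flags_dict())
        row["score"] = r.score
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["person_id", "algorithm", *CONDITION_ORDER, "score"]
    )
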