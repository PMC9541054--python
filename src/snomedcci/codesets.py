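"""Condition code sets and Charlson comorbidity definitions.

A :class:`Codeset` is a named set of codes in one vocabulary. Entries ending
in ``*`` are prefix patterns (``"428*"`` matches any code starting ``428``
after normalization), the form in which the bundled Quan enhanced ICD-9-CM
and ICD-10-CM lists are shipped; enumerated sets (e.g. SNOMED sets produced
by the crosswalk) carry exact codes only.

The 17 Charlson conditions carry the Quan-convention weights (1 for the ten
single-weight conditions; 2 for diabetes with chronic complications,
hemiplegia/paraplegia, renal disease and malignancy; 3 for moderate/severe
liver disease; 6 for metastatic solid tumor and AIDS/HIV) and the standard
severity hierarchy: a milder condition's weight is not counted when its
severe counterpart is present (diabetes without -> with complications, mild
-> moderate/severe liver disease, malignancy -> metastatic solid tumor).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from ._util import normalize_code
from .errors import ContractError
from .vocab import ICD9CM, ICD10CM, SNOMED


@dataclass
class Codeset:
    """A named set of codes in a single vocabulary, with per-code provenance.

    ``provenance`` tags each code with how it entered the set: ``quan_icd9``
    / ``quan_icd10`` (bundled source lists), ``translated`` (produced by the
    forward mapping), ``curated_in`` / ``curated_out`` (expert adjudication).
    """

    name: str
    vocabulary: str
    codes: set[str] = field(default_factory=set)
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._rebuild_index()

    def _rebuild_index(self) -> None:
        self._exact: set[str] = set()
        self._prefixes: list[str] = []
        for c in self.codes:
            n = normalize_code(c)
            if n.endswith("*"):
                self._prefixes.append(n[:-1])
            else:
                self._exact.add(n)
        # longest-first so diagnostics could report the most specific hit
        self._prefixes.sort(key=len, reverse=True)

    def add(self, code: str, provenance: str = "curated_in") -> None:
        self.codes.add(code)
        self.provenance[code] = provenance
        self._rebuild_index()

    def discard(self, code: str) -> None:
        self.codes.discard(code)
        self.provenance.pop(code, None)
        self._rebuild_index()

    def matches(self, code: str) -> bool:
        """Membership test with normalization and prefix-pattern semantics."""
        n = normalize_code(code)
        if n in self._exact:
            return True
        return any(n.startswith(p) for p in self._prefixes)

    def normalized_codes(self) -> frozenset[str]:
        """Normalized exact (non-pattern) codes, for set comparisons."""
        return frozenset(self._exact)

    @property
    def prefixes(self) -> tuple[str, ...]:
        return tuple(self._prefixes)

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return self.matches(code)


# -- the 17 Charlson conditions -------------------------------------------

#: canonical condition order (report rows follow it)
CONDITION_ORDER: tuple[str, ...] = (
    "mi", "chf", "pvd", "cvd", "dementia", "chronic_pulmonary", "rheumatic",
    "pud", "mild_liver", "diabetes_without_cc", "diabetes_with_cc",
    "paralysis", "renal", "malignancy", "severe_liver", "metastatic_tumor",
    "aids_hiv",
)

CONDITION_LABELS: Mapping[str, str] = {
    "mi": "Myocardial infarction",
    "chf": "Congestive heart failure",
    "pvd": "Peripheral vascular disease",
    "cvd": "Cerebrovascular disease",
    "dementia": "Dementia",
    "chronic_pulmonary": "Chronic pulmonary disease",
    "rheumatic": "Rheumatic disease",
    "pud": "Peptic ulcer disease",
    "mild_liver": "Mild liver disease",
    "diabetes_without_cc": "Diabetes without chronic complications",
    "diabetes_with_cc": "Diabetes with chronic complications",
    "paralysis": "Hemiplegia or paraplegia",
    "renal": "Renal disease",
    "malignancy": "Malignancy, except skin neoplasms",
    "severe_liver": "Moderate or severe liver disease",
    "metastatic_tumor": "Metastatic solid tumor",
    "aids_hiv": "AIDS/HIV",
}

WEIGHTS: Mapping[str, int] = {
    **{c: 1 for c in CONDITION_ORDER[:10]},
    "diabetes_with_cc": 2, "paralysis": 2, "renal": 2, "malignancy": 2,
    "severe_liver": 3, "metastatic_tumor": 6, "aids_hiv": 6,
}

#: milder condition -> the severe condition that supersedes it in scoring
SUPERSEDED_BY: Mapping[str, str] = {
    "diabetes_without_cc": "diabetes_with_cc",
    "mild_liver": "severe_liver",
    "malignancy": "metastatic_tumor",
}

#: maximum score: all 17 conditions, severity hierarchy applied (33 without)
MAX_SCORE_WITH_HIERARCHY = 29
MAX_SCORE_WITHOUT_HIERARCHY = 33


@dataclass
class ComorbidityDefinition:
    """One Charlson condition: weight, hierarchy link, per-vocabulary codesets."""

    condition: str
    weight: int
    codesets: dict[str, Codeset] = field(default_factory=dict)
    superseded_by: str | None = None

    @property
    def label(self) -> str:
        return CONDITION_LABELS.get(self.condition, self.condition)

    def codeset_for(self, vocabulary: str) -> Codeset | None:
        return self.codesets.get(vocabulary)


# -- interchange IO --------------------------------------------------------

def read_codesets(path: str | Path) -> dict[tuple[str, str], Codeset]:
    """Read codesets from the interchange format.

    One CSV with columns ``condition, vocabulary, code, provenance``; returns
    a mapping keyed by (condition, vocabulary).
    """
    out: dict[tuple[str, str], Codeset] = {}
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        required = {"condition", "vocabulary", "code"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ContractError(
                f"codeset file {path} is missing column(s): {', '.join(sorted(missing))}"
            )
        for row in reader:
            key = (row["condition"], row["vocabulary"])
            cs = out.setdefault(key, Codeset(name=key[0], vocabulary=key[1]))
            cs.codes.add(row["code"])
            cs.provenance[row["code"]] = row.get("provenance", "") or "unspecified"
    for cs in out.values():
        cs._rebuild_index()
    return out


def write_codesets(codesets: Iterable[Codeset], path: str | Path) -> None:
    """Write codesets to the interchange format, sorted for stable diffs."""
    rows = []
    for cs in codesets:
        for code in sorted(cs.codes):
            rows.append((cs.name, cs.vocabulary, code, cs.provenance.get(code, "")))
    rows.sort()
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["condition", "vocabulary", "code", "provenance"])
        w.writerows(rows)


def _packaged(name: str):
    return resources.files("snomedcci.data").joinpath(name)


def load_quan_codesets() -> dict[tuple[str, str], Codeset]:
    """The bundled Quan enhanced ICD-9-CM and ICD-10-CM Charlson code lists."""
    out: dict[tuple[str, str], Codeset] = {}
    for fname in ("quan_icd9cm.csv", "quan_icd10cm.csv"):
        with resources.as_file(_packaged(fname)) as p:
            out.update(read_codesets(p))
    return out


def default_definitions(
    extra_codesets: Mapping[tuple[str, str], Codeset] | None = None,
) -> dict[str, ComorbidityDefinition]:
    """The 17 Charlson definitions with Quan weights and bundled ICD codesets.

    ``extra_codesets`` (e.g. SNOMED sets from the crosswalk, keyed by
    (condition, vocabulary)) are merged in.
    """
    quan = load_quan_codesets()
    defs: dict[str, ComorbidityDefinition] = {}
    for cond in CONDITION_ORDER:
        d = ComorbidityDefinition(
            condition=cond,
            weight=WEIGHTS[cond],
            superseded_by=SUPERSEDED_BY.get(cond),
        )
        for vocab in (ICD9CM, ICD10CM):
            if (cond, vocab) in quan:
                d.codesets[vocab] = quan[(cond, vocab)]
        defs[cond] = d
    if extra_codesets:
        for (cond, vocab), cs in extra_codesets.items():
            if cond not in defs:
                raise ContractError(f"unknown condition {cond!r} in extra codesets")
            defs[cond].codesets[vocab] = cs
    return defs


def reference_counts() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Published per-condition code-overlap and discrepancy-diagnostics tallies
    for a vocabulary-release audit of the Quan-to-SNOMED translation, bundled
    so report arithmetic can be exercised without any licensed vocabulary.

    Returns (overlap, diagnostics) frames: overlap has columns condition,
    vocabulary, both, snomed_only, quan_only; diagnostics has condition,
    information_gain, added_noise, deprecated_unmapped, specificity.
    """
    with resources.as_file(_packaged("reference_code_overlap.csv")) as p:
        overlap = pd.read_csv(p)
    with resources.as_file(_packaged("reference_code_diagnostics.csv")) as p:
        diags = pd.read_csv(p)
    return overlap, diags


__all__ = [
    "Codeset", "ComorbidityDefinition", "CONDITION_ORDER", "CONDITION_LABELS",
    "SUPERSEDED_BY", "MAX_SCORE_WITH_HIERARCHY", "MAX_SCORE_WITHOUT_HIERARCHY",
    "read_codesets", "write_codesets", "load_quan_codesets",
    "default_definitions", "reference_counts",
]
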