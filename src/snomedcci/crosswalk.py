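"""ICD -> SNOMED codeset adaptation with back-translation diagnostics.

The adaptation of a Quan-style ICD condition codeset to SNOMED proceeds in
three steps:

1. *Translate*: forward-map every ICD code in the source set through the
   vocabulary's maps-to edges, yielding an initial SNOMED codeset.
2. *Back-translate and diff*: map the SNOMED set back to ICD (optionally
   through the descendant closure) and partition the union of the source and
   back-mapped sets into codes captured by both algorithms, by the SNOMED
   side only, or by the Quan side only. Codes not captured by both are
   *discrepant*.
3. *Curate*: expert adjudication (read from a file, never inferred) labels
   extra back-mapped codes as information gain or added noise and may
   exclude over-broad SNOMED concepts from the set.

Every discrepant code is classified into exactly one diagnostic category:

* ``multiple_icd_to_one_snomed`` — the code was pulled in because a SNOMED
  concept in the set is the maps-to target of both an in-set and an
  out-of-set ICD code (always the ``snomed_only`` side);
* ``deprecated_unmapped`` — an in-set ICD code with no maps-to edge in this
  snapshot (deprecated codes lose their mappings);
* ``specificity`` — an in-set ICD code lost because its every SNOMED target
  was excluded as mapping too broadly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import normalize_code, pct
from .codesets import CONDITION_ORDER, Codeset
from .errors import ContractError
from .vocab import SNOMED, ForwardMapResult, VocabularyStore, forward_map, reverse_map

SIDES = ("snomed_only", "quan_only")
CATEGORIES = ("multiple_icd_to_one_snomed", "deprecated_unmapped", "specificity")
ADJUDICATIONS = ("information_gain", "added_noise", "pending")


@dataclass(frozen=True)
class DiscrepancyRecord:
    """One discrepant ICD code with its diagnostic category.

    ``adjudication`` carries the expert gain/noise label for
    ``multiple_icd_to_one_snomed`` records ("pending" until adjudicated) and
    is ``None`` for the other categories, which carry no such label.
    ``via_snomed_ids`` lists the SNOMED concept(s) implicated: the retained
    shared targets for a multiple-to-one record, the excluded targets for a
    specificity record, empty for a deprecated code.
    """

    condition: str
    code: str
    vocabulary: str
    side: str
    category: str
    adjudication: str | None = None
    via_snomed_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ContractError(f"unknown side {self.side!r}")
        if self.category not in CATEGORIES:
            raise ContractError(f"unknown category {self.category!r}")
        if self.category == "deprecated_unmapped":
            if self.side != "quan_only" or self.via_snomed_ids:
                raise ContractError(
                    "deprecated_unmapped records must be quan_only with no SNOMED concepts"
                )
        if self.category == "multiple_icd_to_one_snomed":
            if self.adjudication not in ADJUDICATIONS:
                raise ContractError(
                    f"multiple-to-one records need an adjudication label, got {self.adjudication!r}"
                )
        elif self.adjudication is not None:
            raise ContractError(f"{self.category} records carry no adjudication label")


@dataclass
class Adjudication:
    """Expert decisions keyed by SNOMED concept id or by ICD code.

    Decisions: ``information_gain`` / ``added_noise`` annotate the extra
    codes a retained SNOMED concept pulls in; ``exclude`` removes the SNOMED
    concept from the adapted set.
    """

    by_snomed_id: dict[int, str] = field(default_factory=dict)
    by_code: dict[str, str] = field(default_factory=dict)

    _DECISIONS = frozenset({"information_gain", "added_noise", "exclude"})

    def decision_for_concept(self, snomed_id: int) -> str | None:
        return self.by_snomed_id.get(snomed_id)

    def decision_for_code(self, code: str) -> str | None:
        return self.by_code.get(normalize_code(code))

    def excluded_ids(self) -> set[int]:
        return {i for i, d in self.by_snomed_id.items() if d == "exclude"}

    def add(self, key: int | str, decision: str) -> None:
        if decision not in self._DECISIONS:
            raise ContractError(f"unknown adjudication decision {decision!r}")
        if isinstance(key, int):
            self.by_snomed_id[key] = decision
        else:
            self.by_code[normalize_code(key)] = decision

    def validate_against(self, store: VocabularyStore) -> None:
        unknown = [i for i in self.by_snomed_id if i not in store.concepts]
        if unknown:
            raise ContractError(
                f"adjudication references unknown SNOMED concept id(s): "
                f"{', '.join(str(i) for i in sorted(unknown))}"
            )


def read_adjudication(path: str | Path) -> Adjudication:
    """Read an adjudication file (columns: key_type, key, decision, note)."""
    adj = Adjudication()
    with open(path, newline="") as f:
        reader = csv.DictReader(f)
        required = {"key_type", "key", "decision"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise ContractError(
                f"adjudication file missing column(s): {', '.join(sorted(missing))}"
            )
        for row in reader:
            key: int | str
            if row["key_type"] == "snomed_id":
                key = int(row["key"])
            elif row["key_type"] == "code":
                key = row["key"]
            else:
                raise ContractError(f"unknown key_type {row['key_type']!r}")
            adj.add(key, row["decision"])
    return adj


def write_adjudication(adj: Adjudication, path: str | Path) -> None:
    rows = [("snomed_id", str(k), v, "") for k, v in sorted(adj.by_snomed_id.items())]
    rows += [("code", k, v, "") for k, v in sorted(adj.by_code.items())]
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["key_type", "key", "decision", "note"])
        w.writerows(rows)


@dataclass
class CodePartition:
    """Three disjoint sets of normalized codes whose union is the union of
    the source (Quan) and back-mapped codesets."""

    both: frozenset[str]
    snomed_only: frozenset[str]
    quan_only: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.both) + len(self.snomed_only) + len(self.quan_only)


def find_discrepant_codes(
    quan_codes: Iterable[str], backmapped_codes: Iterable[str]
) -> CodePartition:
    """Partition codes by which algorithm captures them (set algebra on
    normalized codes)."""
    q = {normalize_code(c) for c in quan_codes}
    b = {normalize_code(c) for c in backmapped_codes}
    return CodePartition(
        both=frozenset(q & b),
        snomed_only=frozenset(b - q),
        quan_only=frozenset(q - b),
    )


def classify_discrepancy(
    store: VocabularyStore,
    side: str,
    code: str,
    vocabulary: str,
    quan_codes: frozenset[str] | None = None,
) -> str:
    """Diagnostic category of one discrepant code.

    ``quan_codes`` (normalized), when given, enables the contract check that
    the code is actually discrepant from the side claimed.
    """
    if side not in SIDES:
        raise ContractError(f"unknown side {side!r}")
    n = normalize_code(code)
    if quan_codes is not None:
        in_set = n in quan_codes
        if side == "snomed_only" and in_set:
            raise ContractError(f"{code} is in the source set; not snomed_only")
        if side == "quan_only" and not in_set:
            raise ContractError(f"{code} is not in the source set; not quan_only")
    if side == "snomed_only":
        return "multiple_icd_to_one_snomed"
    concept = store.concept_by_code(code, vocabulary)
    has_edges = bool(concept and store.maps_to.get(concept.concept_id))
    return "specificity" if has_edges else "deprecated_unmapped"


@dataclass
class AdaptationResult:
    """Output of one condition's adaptation: the curated SNOMED codeset, the
    discrepancy ledger, the raw translation products, and per-vocabulary
    partitions."""

    condition: str
    snomed_codeset: Codeset
    ledger: list[DiscrepancyRecord]
    forward: ForwardMapResult
    retained_ids: frozenset[int]
    excluded_ids: frozenset[int]
    partitions: dict[str, CodePartition]


def _enumerate_codes(store: VocabularyStore, cs: Codeset) -> set[tuple[str, str]]:
    """Exact codes of ``cs`` present in the store (prefix patterns expanded
    against the snapshot's concept table)."""
    out: set[tuple[str, str]] = set()
    exact = cs.normalized_codes()
    prefixes = cs.prefixes
    for c in store.concepts.values():
        if c.vocabulary != cs.vocabulary:
            continue
        n = normalize_code(c.code)
        if n in exact or any(n.startswith(p) for p in prefixes):
            out.add((c.code, c.vocabulary))
    return out


def adapt_codeset(
    store: VocabularyStore,
    quan_codesets: Codeset | Sequence[Codeset],
    adjudication: Adjudication | None = None,
    include_descendants: bool = True,
) -> AdaptationResult:
    """Adapt one condition's Quan ICD codeset(s) to a curated SNOMED codeset.

    ``quan_codesets`` may be a single ICD codeset or the (ICD-9-CM, ICD-10-CM)
    pair for one condition; both are translated into one SNOMED set, and the
    back-translation diff is kept per source vocabulary. Deterministic given
    its inputs.
    """
    if isinstance(quan_codesets, Codeset):
        quan_codesets = [quan_codesets]
    if not quan_codesets or all(len(cs) == 0 for cs in quan_codesets):
        raise ContractError("source codeset is empty")
    names = {cs.name for cs in quan_codesets}
    if len(names) != 1:
        raise ContractError(f"codesets must belong to one condition, got {sorted(names)}")
    condition = names.pop()
    adj = adjudication or Adjudication()
    adj.validate_against(store)

    # Step 1: translate
    source_codes: set[tuple[str, str]] = set()
    for cs in quan_codesets:
        source_codes |= _enumerate_codes(store, cs)
    fwd = forward_map(store, source_codes)

    # Step 3 exclusions are applied before the back-translation diff so the
    # diff reflects the curated set
    excluded = adj.excluded_ids() & fwd.snomed_ids
    retained = frozenset(fwd.snomed_ids - excluded)

    snomed_cs = Codeset(name=condition, vocabulary=SNOMED)
    for sid in sorted(retained):
        code = store.concepts[sid].code
        snomed_cs.add(code, provenance="translated")

    # Step 2: back-translate and diff, per source vocabulary
    back = reverse_map(store, retained, include_descendants=include_descendants)
    closure = (
        store.descendant_closure(retained) if include_descendants else set(retained)
    )
    ledger: list[DiscrepancyRecord] = []
    partitions: dict[str, CodePartition] = {}
    for cs in quan_codesets:
        vocab = cs.vocabulary
        source_vocab = {c for c, v in source_codes if v == vocab}
        quan_norm = frozenset(normalize_code(c) for c in source_vocab)
        back_vocab = {c for c, v in back if v == vocab}
        part = find_discrepant_codes(source_vocab, back_vocab)
        partitions[vocab] = part

        for code in sorted(part.snomed_only):
            concept = store.concept_by_code(code, vocab)
            printed = concept.code if concept else code  # ledger keeps dotted form
            targets = store.maps_to.get(concept.concept_id, set()) if concept else set()
            via = tuple(sorted(targets & closure))
            label = _gain_noise_label(adj, code, via)
            ledger.append(DiscrepancyRecord(
                condition=condition, code=printed, vocabulary=vocab,
                side="snomed_only", category="multiple_icd_to_one_snomed",
                adjudication=label, via_snomed_ids=via,
            ))
        for code in sorted(part.quan_only):
            category = classify_discrepancy(store, "quan_only", code, vocab, quan_norm)
            concept = store.concept_by_code(code, vocab)
            printed = concept.code if concept else code
            targets = store.maps_to.get(concept.concept_id, set()) if concept else set()
            if targets & closure:
                # by construction a code with a retained target back-maps into
                # the set; reaching here means the snapshot is inconsistent
                raise ContractError(
                    f"{code} has a retained SNOMED target yet fell out of the set"
                )
            ledger.append(DiscrepancyRecord(
                condition=condition, code=printed, vocabulary=vocab,
                side="quan_only", category=category,
                via_snomed_ids=tuple(sorted(targets)) if category == "specificity" else (),
            ))

    ledger.sort(key=lambda r: (r.condition, r.side, r.vocabulary, r.code))
    return AdaptationResult(
        condition=condition,
        snomed_codeset=snomed_cs,
        ledger=ledger,
        forward=fwd,
        retained_ids=retained,
        excluded_ids=frozenset(excluded),
        partitions=partitions,
    )


def _gain_noise_label(adj: Adjudication, code: str, via: tuple[int, ...]) -> str:
    """Gain/noise label for an extra back-mapped code: a per-code decision
    wins, else the label of any implicated SNOMED concept; unadjudicated
    records stay pending."""
    d = adj.decision_for_code(code)
    if d in ("information_gain", "added_noise"):
        return d
    for sid in via:
        d = adj.decision_for_concept(sid)
        if d in ("information_gain", "added_noise"):
            return d
    return "pending"


# -- reporting -------------------------------------------------------------

def ledger_to_frame(ledgers: Mapping[str, Sequence[DiscrepancyRecord]]) -> pd.DataFrame:
    """Flatten per-condition ledgers to one sorted frame (stable diffs)."""
    rows = [
        {
            "condition": r.condition, "side": r.side, "vocabulary": r.vocabulary,
            "code": r.code, "category": r.category,
            "adjudication": r.adjudication or "",
            "via_snomed_ids": ";".join(str(i) for i in r.via_snomed_ids),
        }
        for recs in ledgers.values()
        for r in recs
    ]
    df = pd.DataFrame(
        rows, columns=["condition", "side", "vocabulary", "code", "category",
                       "adjudication", "via_snomed_ids"],
    )
    return df.sort_values(["condition", "side", "code"], ignore_index=True)


def diagnostics_table(ledgers: Mapping[str, Sequence[DiscrepancyRecord]]) -> pd.DataFrame:
    """Per-condition discrepancy counts by category, with the gain/noise
    split of multiple-to-one records and a grand-total row."""
    cols = ["information_gain", "added_noise", "pending",
            "deprecated_unmapped", "specificity"]
    data = {c: dict.fromkeys(cols, 0) for c in CONDITION_ORDER}
    for recs in ledgers.values():
        for r in recs:
            row = data.setdefault(r.condition, dict.fromkeys(cols, 0))
            if r.category == "multiple_icd_to_one_snomed":
                row[r.adjudication] += 1
            else:
                row[r.category] += 1
    df = pd.DataFrame.from_dict(data, orient="index")[cols]
    df.index.name = "condition"
    df["multiple_icd_to_one_snomed"] = (
        df["information_gain"] + df["added_noise"] + df["pending"]
    )
    df["total"] = (
        df["multiple_icd_to_one_snomed"] + df["deprecated_unmapped"] + df["specificity"]
    )
    df.loc["total"] = df.sum(axis=0)
    return df.reset_index()


def code_overlap_table(
    partitions: Mapping[tuple[str, str], CodePartition]
) -> pd.DataFrame:
    """Per-(condition, vocabulary) both/only counts with one-decimal shares.

    Percentages use the row's code union as denominator, half-up rounding.
    """
    rows = []
    for (cond, vocab), p in sorted(partitions.items()):
        n = p.union_size
        rows.append({
            "condition": cond, "vocabulary": vocab,
            "both": len(p.both), "snomed_only": len(p.snomed_only),
            "quan_only": len(p.quan_only),
            "both_pct": pct(len(p.both), n),
            "snomed_only_pct": pct(len(p.snomed_only), n),
            "quan_only_pct": pct(len(p.quan_only), n),
        })
    return pd.DataFrame(rows)


def audit_shares(overlap: pd.DataFrame, diagnostics: pd.DataFrame) -> dict[str, float]:
    """Headline percentages of a crosswalk audit, computed from count tables.

    ``overlap`` needs columns both/snomed_only/quan_only (one row per
    condition x vocabulary); ``diagnostics`` needs per-condition
    information_gain/added_noise/deprecated_unmapped/specificity counts.
    All shares are half-up rounded to one decimal.
    """
    cond_rows = diagnostics[diagnostics["condition"] != "total"] \
        if "condition" in diagnostics else diagnostics
    gain = int(cond_rows["information_gain"].sum())
    noise = int(cond_rows["added_noise"].sum())
    pending = int(cond_rows["pending"].sum()) if "pending" in cond_rows else 0
    deprecated = int(cond_rows["deprecated_unmapped"].sum())
    specificity = int(cond_rows["specificity"].sum())
    multiple = gain + noise + pending
    discrepant = multiple + deprecated + specificity

    both = int(overlap["both"].sum())
    total_codes = both + discrepant
    return {
        "n_codes": float(total_codes),
        "n_discrepant": float(discrepant),
        "consistent_share_pct": pct(both, total_codes),
        "discrepant_share_pct": pct(discrepant, total_codes),
        "multiple_to_one_share_pct": pct(multiple, discrepant),
        "gain_within_multiple_share_pct": pct(gain, multiple),
        "deprecated_share_pct": pct(deprecated, discrepant),
        "specificity_share_pct": pct(specificity, discrepant),
    }
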