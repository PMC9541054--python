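"""Synthetic vocabularies and claims for desk-scale validation runs.

Two generators, both deterministic for a given spec + seed:

* :func:`gen_vocabulary` builds a miniature vocabulary snapshot engineered
  to contain, per condition and source vocabulary, configurable counts of
  clean 1:1 mappings, multiple-ICD-to-one-SNOMED fan-outs (with gain/noise
  adjudication labels), deprecated unmapped codes, and specificity traps
  (an over-broad SNOMED target the adjudication excludes). Every engineered
  discrepancy carries a ground-truth label, so the crosswalk classifier can
  be scored against the construction. The default spec mirrors the
  per-condition structure of a published audit of the Quan-to-SNOMED
  translation; three replica worked examples (a hypertensive heart/kidney
  disease specificity trap, a migraine-with-cerebral-infarction information
  gain, and a diabetic-kidney-disease fan-out with secondary/drug-induced
  noise codes) are included by default.

* :func:`gen_claims` builds a claims bundle around planted condition flags:
  each planted condition is realized as diagnosis records inside the
  lookback window (an ICD record plus its mapped SNOMED record), discordant
  evidence is drawn from the engineered discrepancy codes so it is visible
  to exactly one coding algorithm, and death follows a Bernoulli draw with
  ``logit p = intercept + slope * true CCI``, placed uniformly within the
  one-year follow-up. Flags are planted directly (flags -> codes) rather
  than via a disease model so ground truth is exact for recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .codesets import CONDITION_ORDER, SUPERSEDED_BY, WEIGHTS, Codeset, reference_counts
from .cohort import ClaimsBundle
from .crosswalk import Adjudication
from .errors import SpecError
from .vocab import ICD9CM, ICD10CM, SNOMED, Concept, VocabularyStore

# -- vocabulary generator --------------------------------------------------

@dataclass(frozen=True)
class StructureCounts:
    """Engineered mapping structures for one (condition, vocabulary) cell."""

    clean: int = 0
    fanout_gain: int = 0    # extra back-mapped codes labelled information gain
    fanout_noise: int = 0   # extra back-mapped codes labelled added noise
    deprecated: int = 0     # in-set codes with no maps-to edge
    specificity: int = 0    # in-set codes whose only target is excluded

    def __post_init__(self) -> None:
        if min(self.clean, self.fanout_gain, self.fanout_noise,
               self.deprecated, self.specificity) < 0:
            raise SpecError("structure counts must be non-negative")


@dataclass
class VocabSpec:
    """Specification of a synthetic vocabulary snapshot."""

    counts: dict[tuple[str, str], StructureCounts] = field(default_factory=dict)
    include_worked_examples: bool = True
    seed: int = 0


@dataclass(frozen=True)
class GroundTruthLabel:
    """The generator's record of one engineered discrepant code."""

    condition: str
    code: str
    vocabulary: str
    side: str        # snomed_only | quan_only
    category: str    # multiple_icd_to_one_snomed | deprecated_unmapped | specificity
    adjudication: str | None = None  # gain/noise for fan-out codes


@dataclass
class ConditionPools:
    """Code material for the claims generator, per condition.

    Tuples are (icd_code, icd_vocabulary, snomed_code); ``snomed_code`` is
    None where no SNOMED record exists (deprecated codes).
    """

    concordant: list[tuple[str, str, str]] = field(default_factory=list)
    snomed_only: list[tuple[str, str, str]] = field(default_factory=list)
    quan_only: list[tuple[str, str, str | None]] = field(default_factory=list)


@dataclass
class SyntheticVocabulary:
    """A generated snapshot with its ground truth."""

    store: VocabularyStore
    quan_codesets: dict[tuple[str, str], Codeset]
    adjudication: Adjudication
    labels: list[GroundTruthLabel]
    expected_snomed: dict[str, set[str]]  # condition -> curated SNOMED codes
    pools: dict[str, ConditionPools]
    spec: VocabSpec


def default_vocab_spec(seed: int = 0, include_worked_examples: bool = True) -> VocabSpec:
    """Per-condition structure counts mirroring the published audit tables.

    Clean counts are the per-vocabulary "both" tallies minus one in-set
    partner per fan-out target; fan-out counts are the "SNOMED-only"
    tallies with the gain/noise split taken from the diagnostics table
    (gain assigned to ICD-10-CM cells first); deprecated and specificity
    counts follow the diagnostics table and sit in ICD-10-CM, where the
    audit located them.
    """
    overlap, diags = reference_counts()
    diags = diags.set_index("condition")
    counts: dict[tuple[str, str], StructureCounts] = {}
    for cond in CONDITION_ORDER:
        gain_budget = int(diags.loc[cond, "information_gain"])
        for vocab in (ICD10CM, ICD9CM):  # gain allocated to ICD-10-CM first
            row = overlap[(overlap["condition"] == cond)
                          & (overlap["vocabulary"] == vocab)]
            if row.empty:
                continue
            fanout = int(row["snomed_only"].iloc[0])
            gain = min(gain_budget, fanout)
            gain_budget -= gain
            dep = int(diags.loc[cond, "deprecated_unmapped"]) if vocab == ICD10CM else 0
            spec_n = int(diags.loc[cond, "specificity"]) if vocab == ICD10CM else 0
            counts[(cond, vocab)] = StructureCounts(
                clean=int(row["both"].iloc[0]),
                fanout_gain=gain,
                fanout_noise=fanout - gain,
                deprecated=dep,
                specificity=spec_n,
            )
    return VocabSpec(counts=counts, seed=seed,
                     include_worked_examples=include_worked_examples)


def small_vocab_spec(seed: int = 0, include_worked_examples: bool = False) -> VocabSpec:
    """A fast all-category spec: every condition gets a couple of each
    structure (handy for unit and property tests)."""
    counts = {}
    for i, cond in enumerate(CONDITION_ORDER):
        for vocab in (ICD9CM, ICD10CM):
            counts[(cond, vocab)] = StructureCounts(
                clean=3, fanout_gain=1 + (i % 2), fanout_noise=1,
                deprecated=i % 2, specificity=(i + 1) % 2,
            )
    return VocabSpec(counts=counts, seed=seed,
                     include_worked_examples=include_worked_examples)


class _IdGen:
    def __init__(self, start: int = 1):
        self._c = itertools.count(start)

    def __call__(self) -> int:
        return next(self._c)


def gen_vocabulary(spec: VocabSpec | None = None) -> SyntheticVocabulary:
    """Build a synthetic vocabulary snapshot with labelled discrepancies."""
    spec = spec or default_vocab_spec()
    concepts: list[Concept] = []
    edges: list[tuple[int, int]] = []
    quan: dict[tuple[str, str], Codeset] = {}
    adj = Adjudication()
    labels: list[GroundTruthLabel] = []
    expected: dict[str, set[str]] = {c: set() for c in CONDITION_ORDER}
    pools: dict[str, ConditionPools] = {c: ConditionPools() for c in CONDITION_ORDER}

    new_id = _IdGen(1_000_001)
    serial = _IdGen(1)

    def icd_code(vocab: str) -> str:
        tag = "9" if vocab == ICD9CM else "0"
        return f"X{tag}{serial():05d}"

    def add_concept(code: str, vocab: str, name: str = "", valid: bool = True) -> int:
        cid = new_id()
        concepts.append(Concept(cid, code, vocab, name, valid))
        return cid

    def add_snomed(name: str = "") -> tuple[int, str]:
        cid = new_id()
        code = str(cid)
        concepts.append(Concept(cid, code, SNOMED, name))
        return cid, code

    def quan_set(cond: str, vocab: str) -> Codeset:
        return quan.setdefault((cond, vocab),
                               Codeset(name=cond, vocabulary=vocab))

    for (cond, vocab) in sorted(spec.counts):
        sc = spec.counts[(cond, vocab)]
        cs = quan_set(cond, vocab)
        pool = pools[cond]

        n_fanout_codes = sc.fanout_gain + sc.fanout_noise
        n_targets = min(sc.clean, n_fanout_codes) if n_fanout_codes else 0
        if n_fanout_codes and sc.clean == 0:
            raise SpecError(
                f"{cond}/{vocab}: fan-outs need at least one clean in-set partner"
            )
        n_plain_clean = sc.clean - n_targets

        # clean 1:1 mappings
        for _ in range(n_plain_clean):
            c = icd_code(vocab)
            cid = add_concept(c, vocab)
            sid, scode = add_snomed()
            edges.append((cid, sid))
            cs.add(c, provenance="quan_icd9" if vocab == ICD9CM else "quan_icd10")
            expected[cond].add(scode)
            pool.concordant.append((c, vocab, scode))

        # fan-out targets: one in-set partner each, out-of-set codes spread
        # round-robin; the first `fanout_gain` out-of-set codes (generation
        # order) are adjudicated information gain, the rest added noise
        fan_targets: list[tuple[int, str]] = []
        for _ in range(n_targets):
            a = icd_code(vocab)
            aid = add_concept(a, vocab)
            sid, scode = add_snomed()
            edges.append((aid, sid))
            cs.add(a, provenance="quan_icd9" if vocab == ICD9CM else "quan_icd10")
            expected[cond].add(scode)
            fan_targets.append((sid, scode))
            pool.concordant.append((a, vocab, scode))
        for k in range(n_fanout_codes):
            sid, scode = fan_targets[k % n_targets]
            b = icd_code(vocab)
            bid = add_concept(b, vocab)
            edges.append((bid, sid))
            decision = "information_gain" if k < sc.fanout_gain else "added_noise"
            adj.add(b, decision)
            labels.append(GroundTruthLabel(
                cond, b, vocab, "snomed_only", "multiple_icd_to_one_snomed", decision))
            pool.snomed_only.append((b, vocab, scode))

        # deprecated in-set codes: no maps-to edge in this snapshot
        for _ in range(sc.deprecated):
            c = icd_code(vocab)
            add_concept(c, vocab, valid=False)
            cs.add(c, provenance="quan_icd9" if vocab == ICD9CM else "quan_icd10")
            labels.append(GroundTruthLabel(
                cond, c, vocab, "quan_only", "deprecated_unmapped"))
            pool.quan_only.append((c, vocab, None))

        # specificity traps: in-set code whose sole target also back-maps to
        # an out-of-scope code; the adjudication excludes the target
        for _ in range(sc.specificity):
            c = icd_code(vocab)
            cid = add_concept(c, vocab)
            sid, scode = add_snomed()
            edges.append((cid, sid))
            d = icd_code(vocab)
            did = add_concept(d, vocab)
            edges.append((did, sid))
            cs.add(c, provenance="quan_icd9" if vocab == ICD9CM else "quan_icd10")
            adj.add(sid, "exclude")
            labels.append(GroundTruthLabel(
                cond, c, vocab, "quan_only", "specificity"))
            pool.quan_only.append((c, vocab, scode))

    if spec.include_worked_examples:
        _add_worked_examples(concepts, edges, quan_set, adj, labels, expected, pools,
                             add_concept, add_snomed)

    store = VocabularyStore.from_concepts(concepts, edges)
    return SyntheticVocabulary(
        store=store, quan_codesets=quan, adjudication=adj, labels=labels,
        expected_snomed=expected, pools=pools, spec=spec,
    )


def _add_worked_examples(concepts, edges, quan_set, adj, labels, expected, pools,
                         add_concept, add_snomed) -> None:
    """Replicas of three canonical crosswalk failure modes.

    * hypertensive heart & chronic kidney disease: the in-set code I13.2 maps
      only to an over-broad concept that also back-maps to I13.1, so the
      concept is excluded and I13.2 is lost (specificity);
    * persistent migraine aura with cerebral infarction: G43.61 shares the
      cerebral-infarction concept with the in-set I63.9 and is judged
      clinically relevant (information gain);
    * disorder of kidney due to diabetes mellitus: one concept fans out to
      in-set diabetic-complication codes (250.4, E13.2) and to secondary /
      drug-induced diabetes codes (249.4, E09.2) judged added noise.
    """
    # specificity trap (CHF)
    chf = quan_set("chf", ICD10CM)
    i132 = add_concept("I13.2", ICD10CM, "hypertensive heart and CKD with heart failure")
    i131 = add_concept("I13.1", ICD10CM, "hypertensive heart and CKD without heart failure")
    broad_id = add_concept("44784621", SNOMED, "hypertensive heart and chronic kidney disease")
    edges += [(i132, broad_id), (i131, broad_id)]
    chf.add("I13.2", provenance="quan_icd10")
    adj.add(broad_id, "exclude")
    labels.append(GroundTruthLabel("chf", "I13.2", ICD10CM, "quan_only", "specificity"))
    pools["chf"].quan_only.append(("I13.2", ICD10CM, "44784621"))

    # information gain (CVD)
    cvd = quan_set("cvd", ICD10CM)
    i639 = add_concept("I63.9", ICD10CM, "cerebral infarction, unspecified")
    g4361 = add_concept("G43.61", ICD10CM,
                        "persistent migraine aura with cerebral infarction")
    ci_id = add_concept("443454", SNOMED, "cerebral infarction")
    edges += [(i639, ci_id), (g4361, ci_id)]
    cvd.add("I63.9", provenance="quan_icd10")
    adj.add("G43.61", "information_gain")
    labels.append(GroundTruthLabel("cvd", "G43.61", ICD10CM, "snomed_only",
                                   "multiple_icd_to_one_snomed", "information_gain"))
    expected["cvd"].add("443454")
    pools["cvd"].concordant.append(("I63.9", ICD10CM, "443454"))
    pools["cvd"].snomed_only.append(("G43.61", ICD10CM, "443454"))

    # fan-out with added noise (diabetes with chronic complications)
    dm9 = quan_set("diabetes_with_cc", ICD9CM)
    dm10 = quan_set("diabetes_with_cc", ICD10CM)
    kid_id = add_concept("192279", SNOMED, "disorder of kidney due to diabetes mellitus")
    c2504 = add_concept("250.4", ICD9CM, "diabetes with renal manifestations")
    ce132 = add_concept("E13.2", ICD10CM, "other specified diabetes with kidney complications")
    c2494 = add_concept("249.4", ICD9CM, "secondary diabetes with renal manifestations")
    ce092 = add_concept("E09.2", ICD10CM, "drug or chemical induced diabetes with kidney complications")
    edges += [(c2504, kid_id), (ce132, kid_id), (c2494, kid_id), (ce092, kid_id)]
    dm9.add("250.4", provenance="quan_icd9")
    dm10.add("E13.2", provenance="quan_icd10")
    for code, vocab in (("249.4", ICD9CM), ("E09.2", ICD10CM)):
        adj.add(code, "added_noise")
        labels.append(GroundTruthLabel("diabetes_with_cc", code, vocab, "snomed_only",
                                       "multiple_icd_to_one_snomed", "added_noise"))
        pools["diabetes_with_cc"].snomed_only.append((code, vocab, "192279"))
    expected["diabetes_with_cc"].add("192279")
    pools["diabetes_with_cc"].concordant.append(("250.4", ICD9CM, "192279"))
    pools["diabetes_with_cc"].concordant.append(("E13.2", ICD10CM, "192279"))


# -- claims generator ------------------------------------------------------

#: default per-condition prevalences (inpatient Medicaid-like case mix)
DEFAULT_PREVALENCE: Mapping[str, float] = {
    "mi": 0.147, "chf": 0.263, "pvd": 0.251, "cvd": 0.248, "dementia": 0.100,
    "chronic_pulmonary": 0.532, "rheumatic": 0.075, "pud": 0.069,
    "mild_liver": 0.210, "diabetes_without_cc": 0.368, "diabetes_with_cc": 0.252,
    "paralysis": 0.085, "renal": 0.217, "malignancy": 0.123,
    "severe_liver": 0.031, "metastatic_tumor": 0.040, "aids_hiv": 0.015,
}


@dataclass
class ClaimsSpec:
    """Specification of a synthetic claims bundle.

    ``snomed_only_rate`` / ``quan_only_rate`` are per planted
    condition-occurrence probabilities that the evidence is drawn from
    discrepancy codes visible to exactly one algorithm.
    """

    n_patients: int = 20_000
    calendar_year: int = 2018
    prevalence: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE))
    snomed_only_rate: float = 0.02
    quan_only_rate: float = 0.001
    mortality_intercept: float = -3.0
    mortality_slope: float = 0.25
    eligible_fraction: float = 0.90
    underage_fraction: float = 0.02
    p_male: float = 0.40
    seed: int = 0

    def validate(self) -> "ClaimsSpec":
        if self.n_patients < 1:
            raise SpecError("n_patients must be >= 1")
        for cond, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"prevalence for {cond} out of [0, 1]: {p}")
        for name in ("snomed_only_rate", "quan_only_rate", "eligible_fraction",
                     "underage_fraction", "p_male"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} out of [0, 1]: {v}")
        if self.snomed_only_rate + self.quan_only_rate > 1.0:
            raise SpecError("discordance rates sum above 1")
        return self


@dataclass
class SyntheticClaims:
    """A generated claims bundle with its ground truth."""

    bundle: ClaimsBundle
    truth: pd.DataFrame  # person_id, eligible, <flags...>, cci_true, died
    spec: ClaimsSpec


def true_cci(flags: Mapping[str, bool]) -> int:
    """Weighted score of planted flags, severity hierarchy applied."""
    score = 0
    for cond in CONDITION_ORDER:
        if not flags[cond]:
            continue
        severe = SUPERSEDED_BY.get(cond)
        if severe and flags.get(severe):
            continue
        score += WEIGHTS[cond]
    return score


def gen_claims(
    spec: ClaimsSpec | None = None,
    vocabulary: SyntheticVocabulary | None = None,
) -> SyntheticClaims:
    """Generate a claims bundle with planted condition flags.

    ``vocabulary`` supplies the code pools; the source vocabulary is chosen
    by calendar year (ICD-9-CM era through 2015, ICD-10-CM after), matching
    how claims extracts switch coding systems.
    """
    spec = (spec or ClaimsSpec()).validate()
    vocabulary = vocabulary or gen_vocabulary(small_vocab_spec())
    rng = np.random.default_rng(spec.seed)
    year = spec.calendar_year
    vocab = ICD9CM if year <= 2015 else ICD10CM

    n = spec.n_patients
    person_ids = np.arange(1, n + 1)

    underage = rng.random(n) < spec.underage_fraction
    yob = rng.integers(1930, year - 18 + 1, size=n)
    yob[underage] = year - rng.integers(1, 18, size=int(underage.sum()))
    sex = np.where(rng.random(n) < spec.p_male, "M", "F")

    # index inpatient visit, uniform over the calendar year
    year_start = pd.Timestamp(year=year, month=1, day=1)
    n_days = 366 if year_start.is_leap_year else 365
    index_offset = rng.integers(0, n_days, size=n)
    index_date = year_start + pd.to_timedelta(index_offset, unit="D")

    # observation periods: eligible persons covered over the full lookback,
    # the rest enrolled too recently
    eligible_obs = rng.random(n) < spec.eligible_fraction
    pre_days = np.where(eligible_obs,
                        366 + rng.integers(0, 1000, size=n),
                        rng.integers(0, 300, size=n))
    post_days = rng.integers(400, 500, size=n)
    obs_start = index_date - pd.to_timedelta(pre_days, unit="D")
    obs_end = index_date + pd.to_timedelta(post_days, unit="D")

    visits = pd.DataFrame({
        "person_id": person_ids,
        "visit_id": person_ids * 10,
        "visit_start": index_date,
        "visit_type": "IP",
    })
    # a later second inpatient visit for some, so earliest-visit indexing matters
    second = rng.random(n) < 0.2
    room = (pd.Timestamp(year=year, month=12, day=31) - index_date).days.to_numpy()
    has_second = second & (room > 0)
    if has_second.any():
        extra_off = rng.integers(1, np.maximum(room[has_second], 1) + 1)
        visits = pd.concat([visits, pd.DataFrame({
            "person_id": person_ids[has_second],
            "visit_id": person_ids[has_second] * 10 + 1,
            "visit_start": index_date[has_second] + pd.to_timedelta(extra_off, unit="D"),
            "visit_type": "IP",
        })], ignore_index=True)

    # planted flags
    flags = {}
    for cond in CONDITION_ORDER:
        p = spec.prevalence.get(cond, 0.0)
        flags[cond] = rng.random(n) < p
    cci = np.array([
        true_cci({c: bool(flags[c][i]) for c in CONDITION_ORDER}) for i in range(n)
    ])

    # condition occurrences: each planted flag realized as >=1 record inside
    # the lookback window
    pools = vocabulary.pools
    occ_person: list[int] = []
    occ_code: list[str] = []
    occ_vocab: list[str] = []
    occ_date: list[pd.Timestamp] = []

    def emit(pid: int, code: str, voc: str, when: pd.Timestamp) -> None:
        occ_person.append(pid)
        occ_code.append(code)
        occ_vocab.append(voc)
        occ_date.append(when)

    for cond in CONDITION_ORDER:
        pool = pools[cond]
        conc = [t for t in pool.concordant if t[1] == vocab]
        s_only = [t for t in pool.snomed_only if t[1] == vocab]
        q_only = [t for t in pool.quan_only if t[1] == vocab]
        idxs = np.flatnonzero(flags[cond])
        if len(idxs) == 0 or not conc:
            continue
        mode_draw = rng.random(len(idxs))
        lag = rng.integers(0, 366, size=len(idxs))
        pick = rng.integers(0, 1 << 30, size=len(idxs))
        for j, i in enumerate(idxs):
            pid = int(person_ids[i])
            when = index_date[i] - pd.Timedelta(days=int(lag[j]))
            if s_only and mode_draw[j] < spec.snomed_only_rate:
                code, voc, scode = s_only[pick[j] % len(s_only)]
                emit(pid, code, voc, when)
                emit(pid, scode, SNOMED, when)
            elif q_only and mode_draw[j] < spec.snomed_only_rate + spec.quan_only_rate:
                code, voc, scode = q_only[pick[j] % len(q_only)]
                emit(pid, code, voc, when)
                if scode is not None:  # excluded concept: invisible to the curated set
                    emit(pid, scode, SNOMED, when)
            else:
                code, voc, scode = conc[pick[j] % len(conc)]
                emit(pid, code, voc, when)
                emit(pid, scode, SNOMED, when)

    # mortality on the true CCI
    logit = spec.mortality_intercept + spec.mortality_slope * cci
    p_death = 1.0 / (1.0 + np.exp(-logit))
    died = rng.random(n) < p_death
    death_lag = rng.integers(0, 366, size=n)
    death_date = index_date + pd.to_timedelta(death_lag, unit="D")

    bundle = ClaimsBundle(
        persons=pd.DataFrame({
            "person_id": person_ids, "year_of_birth": yob, "sex": sex,
        }),
        observation_periods=pd.DataFrame({
            "person_id": person_ids,
            "start_date": obs_start.strftime("%Y-%m-%d"),
            "end_date": obs_end.strftime("%Y-%m-%d"),
        }),
        visits=visits.assign(
            visit_start=lambda d: pd.to_datetime(d["visit_start"]).dt.strftime("%Y-%m-%d")
        ),
        condition_occurrences=pd.DataFrame({
            "person_id": occ_person, "code": occ_code, "vocabulary": occ_vocab,
            "date": [d.strftime("%Y-%m-%d") for d in occ_date],
        }),
        deaths=pd.DataFrame({
            "person_id": person_ids[died],
            "death_date": death_date[died].strftime("%Y-%m-%d"),
        }),
    ).validate()

    truth = pd.DataFrame({"person_id": person_ids, "eligible_obs": eligible_obs,
                          "underage": underage})
    for cond in CONDITION_ORDER:
        truth[cond] = flags[cond]
    truth["cci_true"] = cci
    truth["died"] = died
    return SyntheticClaims(bundle=bundle, truth=truth, spec=spec)
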