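"""End-to-end validation runs: adapt -> score -> compare, with file outputs.

A run takes a vocabulary snapshot plus per-condition source codesets (or
generates the synthetic defaults), adapts every condition's codeset to
SNOMED with discrepancy diagnostics, builds the calendar-year cohort from a
claims bundle (real or synthetic), scores each patient under the SNOMED and
the vocabulary-appropriate Quan algorithm, and emits:

* ``attrition.csv`` — cohort exclusion accounting;
* ``balance.csv`` — CCI and per-condition prevalences with SMDs;
* ``patient_overlap.csv`` — per-condition both/neither/only patient counts;
* ``code_overlap.csv`` / ``diagnostics.csv`` / ``ledger.csv`` — the
  crosswalk audit tables;
* ``model_performance.csv`` — logistic one-year-mortality models and
  c-statistics per algorithm;
* ``snomed_codesets.csv`` — the adapted SNOMED codesets (interchange format);
* ``summary.txt`` and ``manifest.json`` — run summary and reproducibility
  manifest (config echo, derived seeds, config hash).

All randomness flows from one top-level seed; stage substreams are derived
from it with a seed sequence, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cci import ALGORITHM_VOCABULARY, results_frame, score_cohort
from .codesets import CONDITION_ORDER, ComorbidityDefinition, WEIGHTS, SUPERSEDED_BY, \
    Codeset, read_codesets, write_codesets
from .cohort import ClaimsBundle, attach_outcome, build_cohort
from .crosswalk import Adjudication, adapt_codeset, audit_shares, code_overlap_table, \
    diagnostics_table, ledger_to_frame, read_adjudication
from .errors import ContractError
from .synth import ClaimsSpec, SyntheticVocabulary, default_vocab_spec, gen_claims, \
    gen_vocabulary
from .valstats import balance_table, fit_mortality_model, overlap_table
from .vocab import SNOMED, load_vocabulary


@dataclass
class RunConfig:
    """Configuration of one validation run.

    With ``vocab_dir``/``claims_dir`` unset the synthetic defaults are
    generated, which is the desk-scale mode every test exercises.
    """

    out_dir: str = "runs/validation"
    calendar_year: int = 2018
    seed: int = 0
    n_patients: int = 20_000
    # real-data inputs (all-or-nothing per stage)
    vocab_dir: str | None = None          # CONCEPT/CONCEPT_RELATIONSHIP/CONCEPT_ANCESTOR
    vocab_dialect: str = "omop"
    quan_codesets_path: str | None = None  # interchange CSV
    adjudication_path: str | None = None
    claims_dir: str | None = None
    # synthetic-claims knobs
    snomed_only_rate: float = 0.02
    quan_only_rate: float = 0.001
    mortality_intercept: float = -3.0
    mortality_slope: float = 0.25
    # method switches
    include_descendants: bool = True
    apply_hierarchy: bool = True
    n_boot: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ContractError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ValidationReport:
    """In-memory result of :func:`run_validation`."""

    cohort_rows: pd.DataFrame
    attrition: pd.DataFrame
    balance: pd.DataFrame
    patient_overlap: pd.DataFrame
    code_overlap: pd.DataFrame
    diagnostics: pd.DataFrame
    ledger: pd.DataFrame
    shares: dict[str, float]
    performances: list
    snomed_codesets: dict[str, Codeset]
    manifest: dict = field(default_factory=dict)


def _stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage substream seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(3)
    return {
        "claims": int(states[0] % (2 ** 31)),
        "bootstrap": int(states[1] % (2 ** 31)),
        "spare": int(states[2] % (2 ** 31)),
    }


def _build_definitions(
    quan_codesets: dict[tuple[str, str], Codeset],
    snomed_codesets: dict[str, Codeset],
) -> dict[str, ComorbidityDefinition]:
    defs: dict[str, ComorbidityDefinition] = {}
    for cond in CONDITION_ORDER:
        d = ComorbidityDefinition(
            condition=cond, weight=WEIGHTS[cond],
            superseded_by=SUPERSEDED_BY.get(cond),
        )
        for (c, vocab), cs in quan_codesets.items():
            if c == cond:
                d.codesets[vocab] = cs
        if cond in snomed_codesets:
            d.codesets[SNOMED] = snomed_codesets[cond]
        defs[cond] = d
    return defs


def run_validation(config: RunConfig) -> ValidationReport:
    """Execute the full adapt -> score -> compare pipeline and write outputs."""
    seeds = _stage_seeds(config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- vocabulary + source codesets + adjudication
    synth_vocab: SyntheticVocabulary | None = None
    if config.vocab_dir is None:
        synth_vocab = gen_vocabulary(default_vocab_spec(seed=config.seed))
        store = synth_vocab.store
        quan_codesets = synth_vocab.quan_codesets
        adjudication = synth_vocab.adjudication
    else:
        vd = Path(config.vocab_dir)
        store = load_vocabulary(
            vd / "CONCEPT.csv", vd / "CONCEPT_RELATIONSHIP.csv",
            vd / "CONCEPT_ANCESTOR.csv" if (vd / "CONCEPT_ANCESTOR.csv").exists() else None,
            dialect=config.vocab_dialect,
        )
        if config.quan_codesets_path is None:
            raise ContractError("quan_codesets_path is required with vocab_dir")
        quan_codesets = read_codesets(config.quan_codesets_path)
        adjudication = (read_adjudication(config.adjudication_path)
                        if config.adjudication_path else Adjudication())

    # --- crosswalk adaptation, per condition
    snomed_codesets: dict[str, Codeset] = {}
    ledgers: dict[str, list] = {}
    partitions: dict[tuple[str, str], object] = {}
    for cond in CONDITION_ORDER:
        sets = [cs for (c, _), cs in sorted(quan_codesets.items()) if c == cond]
        if not sets:
            continue
        res = adapt_codeset(store, sets, adjudication,
                            include_descendants=config.include_descendants)
        snomed_codesets[cond] = res.snomed_codeset
        ledgers[cond] = res.ledger
        for vocab, part in res.partitions.items():
            partitions[(cond, vocab)] = part

    code_overlap = code_overlap_table(partitions)
    diagnostics = diagnostics_table(ledgers)
    ledger_df = ledger_to_frame(ledgers)
    shares = audit_shares(
        code_overlap, diagnostics[diagnostics["condition"] != "total"]
    )

    definitions = _build_definitions(quan_codesets, snomed_codesets)

    # --- claims + cohort
    if config.claims_dir is None:
        cs_spec = ClaimsSpec(
            n_patients=config.n_patients,
            calendar_year=config.calendar_year,
            snomed_only_rate=config.snomed_only_rate,
            quan_only_rate=config.quan_only_rate,
            mortality_intercept=config.mortality_intercept,
            mortality_slope=config.mortality_slope,
            seed=seeds["claims"],
        )
        if synth_vocab is None:
            raise ContractError("synthetic claims need a synthetic vocabulary")
        bundle = gen_claims(cs_spec, synth_vocab).bundle
    else:
        bundle = ClaimsBundle.read_dir(config.claims_dir)

    cohort = build_cohort(bundle, config.calendar_year)
    cohort = attach_outcome(cohort, bundle.deaths)
    rows = cohort.rows

    # --- scoring under both algorithms
    quan_algorithm = "quan_icd9" if config.calendar_year <= 2015 else "quan_icd10"
    dx = bundle.condition_occurrences
    res_snomed = score_cohort(rows, dx, definitions, "snomed",
                              apply_hierarchy=config.apply_hierarchy)
    res_quan = score_cohort(rows, dx, definitions, quan_algorithm,
                            apply_hierarchy=config.apply_hierarchy)
    frame_snomed = results_frame(res_snomed)
    frame_quan = results_frame(res_quan)

    balance = balance_table(
        frame_snomed["score"].to_numpy(), frame_quan["score"].to_numpy(),
        frame_snomed, frame_quan, label_a="snomed", label_b="quan",
    )
    patient_overlap = overlap_table(frame_snomed, frame_quan)

    outcomes = rows["died_within_365"].to_numpy(dtype=bool)
    performances = []
    for label, frame in (("snomed", frame_snomed), (quan_algorithm, frame_quan)):
        perf = fit_mortality_model(
            frame["score"].to_numpy(dtype=float), outcomes,
            algorithm=label, n_boot=config.n_boot, seed=seeds["bootstrap"],
        )
        performances.append(perf)

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "derived_seeds": seeds,
        "n_eligible": int(len(rows)),
        "quan_algorithm": quan_algorithm,
    }

    report = ValidationReport(
        cohort_rows=rows, attrition=cohort.attrition_frame(), balance=balance,
        patient_overlap=patient_overlap, code_overlap=code_overlap,
        diagnostics=diagnostics, ledger=ledger_df, shares=shares,
        performances=performances, snomed_codesets=snomed_codesets,
        manifest=manifest,
    )
    _write_report(report, out)
    return report


def _write_report(report: ValidationReport, out: Path) -> None:
    ff = "%.10g"
    report.attrition.to_csv(out / "attrition.csv", index=False)
    report.balance.to_csv(out / "balance.csv", index=False, float_format=ff)
    report.patient_overlap.to_csv(out / "patient_overlap.csv", index=False)
    report.code_overlap.to_csv(out / "code_overlap.csv", index=False, float_format=ff)
    report.diagnostics.to_csv(out / "diagnostics.csv", index=False)
    report.ledger.to_csv(out / "ledger.csv", index=False)
    write_codesets(report.snomed_codesets.values(), out / "snomed_codesets.csv")

    perf_rows = [dataclasses.asdict(p) for p in report.performances]
    pd.DataFrame(perf_rows).to_csv(out / "model_performance.csv", index=False,
                                   float_format=ff)

    with open(out / "manifest.json", "w") as f:
        json.dump(report.manifest, f, indent=2, sort_keys=True)
        f.write("\n")

    lines = ["validation run summary", "======================", ""]
    lines.append(f"eligible patients: {report.manifest['n_eligible']}")
    lines += ["", "crosswalk audit:"]
    for k, v in report.shares.items():
        lines.append(f"  {k}: {v}")
    lines += ["", "mortality models:"]
    for p in report.performances:
        lines.append(
            f"  {p.algorithm}: intercept={p.intercept:.4f} slope={p.slope:.4f} "
            f"c={p.c_statistic:.4f} [{p.ci_low:.4f}, {p.ci_high:.4f}] "
            f"(n={p.n}, events={p.n_events})"
        )
    cci_row = report.balance[report.balance["covariate"] == "cci"].iloc[0]
    lines += ["", (
        "cci mean (snomed vs quan): "
        f"{cci_row['stat_snomed']:.4f} vs {cci_row['stat_quan']:.4f} "
        f"(smd={cci_row['smd']:.4f})"
    )]
    n_imbal = int(report.balance["imbalanced"].sum())
    lines.append(f"imbalanced covariates (smd > 0.10): {n_imbal}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
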