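# snomedcci

Adaptation and validation of a SNOMED CT coding algorithm for the Charlson
Comorbidity Index (CCI) on administrative-claims-shaped data.

## The problem

The CCI summarizes a patient's comorbidity burden as a weighted count of 17
conditions and is the standard covariate for predicting one-year mortality
among hospitalized patients. Its widely used claims implementations — the
Quan enhanced ICD-9-CM and ICD-10-CM code lists — are tied to the ICD
vocabularies, while standardized databases (OMOP CDM) record diagnoses as
SNOMED CT concepts. Porting a condition codeset between vocabularies through
maps-to relationships is lossy in three characteristic ways: several ICD
codes can share one SNOMED concept (so the SNOMED set silently captures
extra codes — clinically relevant *information gain* or *added noise*),
deprecated ICD codes carry no mapping at all, and an in-set code can map
only to a concept too broad to keep (*specificity* loss).

This package is for epidemiologists and medical informaticians who need to
(a) build a curated SNOMED codeset from an ICD one with a fully auditable
discrepancy ledger, and (b) check that the ported algorithm behaves like the
original on real or synthetic cohorts.

## What it computes

- **Crosswalk adaptation** (`snomedcci.crosswalk`): translate an ICD codeset
  through maps-to edges, back-translate the SNOMED set (optionally through
  the descendant closure), diff against the source, classify every
  discrepant code into `multiple_icd_to_one_snomed` / `deprecated_unmapped`
  / `specificity`, and apply expert adjudication (gain/noise labels,
  concept exclusions) read from a file — never inferred.
- **CCI scoring** (`snomedcci.cci`): a condition is flagged when any
  diagnosis in the closed 365-day lookback matches its codeset; the score is
  `CCI = Σᵢ wᵢ·xᵢ` with Quan-convention weights
  (w ∈ {1, 2, 3, 6}) and the usual severity hierarchy (diabetes without →
  with complications, mild → moderate/severe liver disease, malignancy →
  metastatic solid tumor).
- **Cohort construction** (`snomedcci.cohort`): earliest inpatient visit in
  the calendar year as index, age ≥ 18, one observation period covering the
  full lookback, one-year mortality outcome, attrition accounting.
- **Validation statistics** (`snomedcci.valstats`): standardized mean
  differences `SMD = |p₁ − p₂| / √((p₁(1−p₁) + p₂(1−p₂))/2)` (continuous:
  `|m₁ − m₂| / √((s₁² + s₂²)/2)`) with the 0.10 balance threshold,
  per-condition both/neither/only patient overlap, and univariable logistic
  mortality models with the concordance statistic (c = AUC, ties at 0.5) and
  a seeded percentile-bootstrap CI.
- **Synthetic data** (`snomedcci.synth`): miniature vocabularies containing
  every discrepancy category with exact ground-truth labels, and claims
  bundles with planted condition flags, configurable inter-algorithm
  discordance, and death drawn from `logit p = a + b·CCI`.

## Worked example

```bash
python examples/03_synthetic_validation.py
```

prints (4,000 synthetic patients, small planted discordance):

```
                         stage    n
    no_inpatient_visit_in_year    0
                  age_under_18   80
insufficient_prior_observation  378
            death_before_index    0
                      eligible 3542

CCI mean: snomed 3.918 vs quan 3.846  (SMD 0.031)
imbalanced covariates (SMD > 0.10): 0
snomed      c = 0.662 [0.635, 0.686]  slope = 0.238
quan_icd10  c = 0.661 [0.636, 0.685]  slope = 0.239
```

Reading: of 4,000 simulated persons, 3,542 are eligible (the rest fail the
age or continuous-observation filters). The two coding algorithms flag
nearly the same patients, so the CCI means differ by an SMD of 0.031 — well
under the 0.10 imbalance threshold — and their mortality models
discriminate identically to three decimals. The other examples show codeset
adaptation with its ledger (`01`), per-patient scoring with the bundled Quan
lists (`02`), and the audit-share arithmetic on bundled published tallies
(`04`).

The command-line layer wraps the same functions:

```bash
cci simulate --seed 1 --n-patients 5000 --out runs/sim
cci adapt --vocab runs/sim/vocabulary --dialect compact \
    --quan-codesets runs/sim/vocabulary/quan_codesets.csv \
    --adjudication runs/sim/vocabulary/adjudication.csv --out runs/adapted
cci validate --seed 1 --out runs/validation
```

## Layout

```
src/snomedcci/      vocab, codesets, crosswalk, cci, cohort, valstats,
                    synth, report, cli (+ bundled data/*.csv)
examples/           narrative scripts, one per capability
tests/              pytest suite (unit, property, end-to-end)
scripts/acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```

Licensed vocabulary content is never bundled: the toolkit consumes whatever
OMOP-dialect snapshot the user supplies, and ships only a compact fixture
dialect plus synthetic generators for everything else.
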