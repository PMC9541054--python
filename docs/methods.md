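# Methods

## Codeset adaptation

An ICD condition codeset is ported to SNOMED in three steps. *Translate*:
every in-set ICD code contributes **all** of its maps-to targets (no
best-map selection — the diagnostics deliberately count every mapping
path). *Back-translate and diff*: the SNOMED set is mapped back to ICD and
the union of source and back-mapped codes is partitioned into
both / SNOMED-only / Quan-only. *Curate*: an adjudication file supplies
expert decisions — `information_gain` / `added_noise` annotate extra
back-mapped codes, `exclude` removes an over-broad concept. Clinical
relevance is never inferred by the software; unadjudicated fan-out records
stay `pending`.

Discrepant codes are classified exhaustively and mutually exclusively:
SNOMED-only codes are by construction fan-ins (`multiple_icd_to_one_snomed`);
Quan-only codes with no maps-to edge are `deprecated_unmapped`, and with
edges are `specificity` (every target was excluded). A consistency check
enforces that a code with a retained target cannot be Quan-only.

Back-translation expands the SNOMED set to its descendant closure by
default, matching the usual OMOP codeset-expansion convention; the flag
exists because source codesets in the wild are sometimes leaf lists and
sometimes ancestor lists, and the convention is a choice, not a fact about
any particular published codeset.

## Scoring

A condition is flagged iff at least one diagnosis dated within
`[index − 365 d, index]` (closed on both ends; whole-day arithmetic)
matches its codeset in the vocabulary the algorithm reads. Codes are
compared uppercased with dots stripped, since claims extracts disagree on
dotted form; the bundled Quan enhanced ICD-9-CM/ICD-10-CM lists use
trailing-`*` prefix patterns so deep ICD-10-CM codes (e.g. 7-character
forms) match their category. Weights are the Quan-convention Charlson
weights — 1 for the ten single-weight conditions; 2 for diabetes with
chronic complications, hemiplegia/paraplegia, renal disease, malignancy;
3 for moderate/severe liver disease; 6 for metastatic solid tumor and
AIDS/HIV — giving maximum scores of 33 without and 29 with the severity
hierarchy. Hierarchy application defaults on for the score; flag reporting
is independently configurable because descriptive tables conventionally
report both severities (e.g. both diabetes rows at high prevalence) even
when the score counts only the severe one.

## Cohort

Index is the earliest inpatient visit (`visit_type == "IP"`) in the
calendar year, same-day ties broken by lowest visit id. "Continuous
observation" is read strictly: a single observation period must span
`[index − 365 d, index]`; gaps disqualify. Age is calendar year minus year
of birth (claims carry year of birth only). The outcome window is
`[index, index + 365 d]`, closed on both ends; a death recorded before
index is a data anomaly that excludes the person with its own attrition
stage. Attrition stages are applied in a fixed order and always sum back to
the number of input persons.

## Validation statistics

SMDs treat the two algorithm arms as independent groups even though they
score the same patients — the classical two-group formula is what balance
tables conventionally report, and the toolkit reproduces that convention
rather than a paired variant. Zero-spread edge cases return 0 (equal
constants) or +inf (different constants). Percentages in report output are
half-up rounded to one decimal; full precision is kept internally.

The mortality model is a univariable logistic regression (maximum
likelihood via IRLS, parameter-change tolerance 1e-8, 25 iterations max;
non-convergence raises, as does a single-class outcome). The fit is
delegated to statsmodels GLM; the concordance statistic and its CI are
computed here: c is the midrank (rank-sum) formulation, exactly equal to
all-pairs concordance with ties at 0.5, and the CI is a percentile
bootstrap over patients (2,000 resamples by default, seeded; resamples that
lose an outcome class are redrawn, which at study scale never triggers).
Constant scores short-circuit to slope 0 / c 0.5 — the stationary point —
since the design matrix is then singular.

## Synthetic data

The vocabulary generator plants, per condition and source vocabulary,
counts of clean 1:1 mappings, fan-out structures (one in-set partner per
shared concept, extra codes distributed round-robin), deprecated codes, and
specificity traps, each with a ground-truth label; the crosswalk classifier
is required (and tested) to recover 100% of labels. The default spec
mirrors the per-condition structure of a published audit of the
Quan-to-SNOMED translation: 4,648 consistent codes and 553 fan-out, 123
deprecated (all ICD-10-CM) and 12 specificity discrepancies, with each
condition's gain/noise split following the audit's diagnostics table (gain
allocated to ICD-10-CM cells first where the audit does not resolve the
vocabulary). Three replica worked examples — the I13.2-style specificity
trap, the G43.61-style information gain, and the diabetic-kidney fan-out
with secondary/drug-induced noise codes — are included by default.

The claims generator plants condition flags directly (flags → codes) so
ground truth is exact, realizing each planted condition as an ICD record
plus its mapped SNOMED record on the same date inside the lookback.
Discordant evidence draws from the engineered discrepancy codes: an
out-of-set ICD code paired with its retained SNOMED concept is visible only
to the SNOMED algorithm; a deprecated in-set code (or an in-set code whose
concept was excluded) only to the Quan algorithm. Death is Bernoulli with
`logit p = a + b·CCI_true` and a date uniform in the one-year follow-up.
Defaults: 20,000 patients, calendar year 2018 (ICD-10-CM era; 2013-style
runs use ICD-9-CM), per-condition prevalences matching an inpatient
Medicaid-like case mix (MI 0.147 … chronic pulmonary 0.532), intercept −3
and slope 0.25 (implied marginal mortality ≈ 10%), SNOMED-only discordance
0.02 and Quan-only 0.001 per planted occurrence (patient-level only-counts
of a few percent and well under 0.1% respectively), 90% of patients given
eligible observation and 2% underage so the attrition logic is exercised.

What the generator does **not** emulate: disease co-occurrence structure
(flags are independent Bernoulli draws), coding intensity differences
across sites or time, visit-level complexity (transfers, claim collapsing),
incomplete death capture, and any marginal statistics of proprietary
databases. Passing tests therefore demonstrate the *machinery* — exact
ground-truth recovery, oracle agreement, parameter recovery, and the
qualitative finding that small code-level discordance leaves balance and
discrimination essentially unchanged — not performance on any real
population.

## Problem sizes and numerical choices

Test and acceptance runs use 500-patient cohorts for oracle-agreement
checks, 20,000 patients for parameter recovery (slope recovered within
±0.03; between-algorithm c-statistic difference identical at zero
discordance and < 0.01 at the default small discordance), 1,000 random
graphs for the round-trip property, and 100 seeded vocabularies for
classifier recovery — sizes at which every stochastic check has comfortable
margin while the whole suite runs in well under a minute. All stage
randomness derives from one top-level seed via a seed sequence, and report
CSVs are written with fixed float formatting so reruns are byte-identical.

## Known limitations

- Only the maps-to relationship is consumed; no other vocabulary links.
- The bundled reference tallies are transcribed printed tables from a
  vocabulary-release audit and carry that audit's internal rounding and
  tallying quirks; the report code reproduces the arithmetic of whatever
  counts it is fed and does not attempt reconciliation.
- Real SNOMED snapshots are versioned twice a year; adapted codesets are
  snapshot-specific and should be re-audited per release.
- No age adjustment, no Elixhauser or other indices, no multivariable
  modelling or calibration metrics.
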