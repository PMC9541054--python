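"""End-to-end two-algorithm comparison on a synthetic cohort.

Generates the default synthetic vocabulary and a 4,000-patient claims
bundle with a small amount of planted discordance, builds the 2018 cohort,
scores everyone under the SNOMED and Quan ICD-10-CM algorithms, and prints
the balance and discrimination summaries the toolkit writes to disk.
"""

from snomedcci.report import RunConfig, run_validation

cfg = RunConfig(out_dir="runs/example_validation", n_patients=4000,
                seed=1, n_boot=200)
report = run_validation(cfg)

print(report.attrition.to_string(index=False))
cci = report.balance[report.balance["covariate"] == "cci"].iloc[0]
print(f"\nCCI mean: snomed {cci['stat_snomed']:.3f} vs quan {cci['stat_quan']:.3f}"
      f"  (SMD {cci['smd']:.3f})")
print(f"imbalanced covariates (SMD > 0.10): {int(report.balance['imbalanced'].sum())}")
for p in report.performances:
    print(f"{p.algorithm:11s} c = {p.c_statistic:.3f} "
          f"[{p.ci_low:.3f}, {p.ci_high:.3f}]  slope = {p.slope:.3f}")

print("""
Reading: the two coding algorithms flag nearly the same patients, so the CCI
means sit close together (SMD well under the 0.10 balance threshold) and the
mortality-model c-statistics are essentially identical. Full tables are under
runs/example_validation/.
""")
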