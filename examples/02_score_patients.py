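"""Score patients with the bundled Quan enhanced ICD-10-CM code lists.

Two hand-made patients are scored over the 365-day lookback: one with a
myocardial infarction and heart failure, one with malignancy that has
progressed to metastatic disease (showing the severity hierarchy at work).
"""

from datetime import date

from snomedcci import default_definitions
from snomedcci.cci import compute_cci, detect_conditions

defs = default_definitions()
index = date(2018, 6, 1)

mi_chf = [("I21.09", "ICD10CM", date(2018, 3, 1)),   # acute MI
          ("I50.9", "ICD10CM", date(2017, 9, 15))]   # heart failure
flags = detect_conditions(mi_chf, index, defs, "quan_icd10")
print("patient 1 flags:", [c for c, v in flags.items() if v])
print("patient 1 CCI  :", compute_cci(flags, defs))

cancer = [("C34.90", "ICD10CM", date(2018, 1, 10)),  # lung cancer
          ("C78.00", "ICD10CM", date(2018, 5, 2))]   # lung metastases
flags = detect_conditions(cancer, index, defs, "quan_icd10")
print("patient 2 flags:", [c for c, v in flags.items() if v])
print("patient 2 CCI (hierarchy on) :", compute_cci(flags, defs, apply_hierarchy=True))
print("patient 2 CCI (hierarchy off):", compute_cci(flags, defs, apply_hierarchy=False))

print("""
Reading: patient 1 scores 1+1 for MI and CHF. Patient 2 is flagged for both
malignancy (weight 2) and metastatic solid tumor (weight 6); with the
severity hierarchy only the metastatic weight counts (6), without it both
do (8).
""")
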