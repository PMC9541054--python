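"""Adapt ICD condition codesets to SNOMED and read the discrepancy ledger.

Builds a miniature vocabulary containing three canonical crosswalk failure
modes (an over-broad concept that must be excluded, a clinically relevant
extra back-mapped code, and a fan-out pulling in secondary-diabetes noise),
then runs the translate / back-translate / curate adaptation for each
affected condition and prints the resulting ledger.
"""

from snomedcci.crosswalk import adapt_codeset
from snomedcci.synth import VocabSpec, gen_vocabulary

sv = gen_vocabulary(VocabSpec(counts={}, include_worked_examples=True))

for cond in ("chf", "cvd", "diabetes_with_cc"):
    sets = [cs for (c, _), cs in sorted(sv.quan_codesets.items()) if c == cond]
    res = adapt_codeset(sv.store, sets, sv.adjudication)
    print(f"\n{cond}: curated SNOMED set = {sorted(res.snomed_codeset.codes)}")
    for rec in res.ledger:
        print(f"  {rec.code:8s} [{rec.vocabulary}] {rec.side:12s} "
              f"{rec.category:28s} {rec.adjudication or '-'}")

print("""
Reading: the CHF set is empty because its only translated concept back-maps
too broadly and was excluded (I13.2 is ledgered as a specificity loss); the
CVD set keeps the cerebral-infarction concept, whose extra code G43.61 is
information gain; the diabetes set keeps the diabetic-kidney concept while
its secondary/drug-induced codes (249.4, E09.2) are ledgered as added noise.
""")
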