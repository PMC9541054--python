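"""Headline crosswalk-audit percentages from published per-condition tallies.

The package bundles the per-condition code-overlap and discrepancy-category
counts from a published audit of the Quan-to-SNOMED translation (July 2021
SNOMED International release). This example feeds them through the report
arithmetic.
"""

from snomedcci.codesets import reference_counts
from snomedcci.crosswalk import audit_shares

overlap, diagnostics = reference_counts()
shares = audit_shares(overlap, diagnostics)
for key, value in shares.items():
    print(f"{key:32s} {value}")

print("""
Reading: of the 5,343 ICD-9/10-CM codes mapping to either algorithm, 87.0%
are captured by both; 80.6% of the 695 discrepant codes arise from multiple
ICD codes sharing one SNOMED concept, and 24.6% of those represent
information gain rather than noise.
""")
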