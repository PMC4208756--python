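"""Test characteristics of published 2x2 tables on signs of pulmonary
hypertension.

Each shipped table cross-classifies a physical finding (e.g. a loud
pulmonic second heart sound) against catheterization-proven disease.
For every table we compute sensitivity and specificity with Wilson 95%
CIs and likelihood ratios with log-method 95% CIs; tables containing a
zero cell are continuity-corrected (0.5 added to all cells) first.
"""

from phexam import accuracy_summary, pool_tables
from phexam.literature import HARRIS_CONTROLS, LITERATURE_TABLES

for entry in LITERATURE_TABLES:
    est = accuracy_summary(entry.table)
    print(f"{entry.study} — {entry.finding}")
    print(f"  cells (TP,FP,FN,TN) = {entry.table.cells}")
    print(f"  {est.format_row()}")

# The 1968 case series reported no false positives on its own; adding the
# companion normal-subject series supplies the controls, and summing the
# cells reproduces the combined loud-P2 row.
cases = LITERATURE_TABLES[1].table
combined = pool_tables([cases, HARRIS_CONTROLS])
print(f"\ncase series {cases.cells} + controls {HARRIS_CONTROLS.cells}"
      f" -> pooled {combined.cells}")
print("pooled:", accuracy_summary(combined).format_row())

# Reading: LR+ multiplies the pre-test odds of disease when the finding is
# present; an LR+ of 56 makes a loud P2 (phonocardiographically assessed)
# nearly diagnostic in that cohort, while the wide CI reflects the single
# false positive it rests on.
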