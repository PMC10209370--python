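"""Group discrimination statistics on simulated maximum-slope output.

Simulates an HCC and a background-liver group, computes the
maximum-slope HPI for each subject, and runs the study-style group
comparison: ROC AUC with Mann-Whitney p, and a mean/SD/median summary
table per group.  No compartment fitting is involved, so this runs in
seconds.
"""

import pandas as pd

import liverkin as lk
from liverkin.experiment import maxslope_hpi
from liverkin.stats import compare_groups

cohort = lk.simulate_cohort(n_per_group=10, noise_cv=0.02, seed=2)

rows = []
for subj in cohort.subjects_short:
    try:
        rows.append({"group": subj.group, "hpi": maxslope_hpi(subj)})
    except Exception:
        pass  # a degenerate noise draw can defeat the gamma fits

df = pd.DataFrame(rows).dropna()
res = compare_groups(df, "hpi", positive="hcc")

print(res.summary.to_string(index=False))
print(f"\nROC AUC (HCC vs liver, maximum-slope HPI): {res.auc:.3f}"
      f"   p = {res.p_value:.2g}")
print(
    "\nAn AUC near 1 means the arterial-fraction index alone separates\n"
    "arterially-fed lesions from portally-fed background liver; 0.5 would\n"
    "mean no discrimination. Separation degrades with frame noise (try\n"
    "noise_cv=0.05): the maximum-slope HPI compresses both groups toward\n"
    "0.5, shrinking the gap between them."
)
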