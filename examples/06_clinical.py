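"""Clinicopathological associations and survival for fusion-positive vs
fusion-negative patients, on a synthetic cohort.

Generates the default 147-patient cohort (47 matched normals) and runs the
association table and Kaplan-Meier comparison against the planted carrier
labels.
"""

from fusionsieve import SimConfig, simulate
from fusionsieve.clinical import association_report, survival_comparison

cohort = simulate(SimConfig(seed=0))
carriers = set(cohort.carriers)
fusion = {r.sample_id: r.sample_id in carriers for r in cohort.clinical}

report = association_report(cohort.clinical, fusion)
print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

surv = survival_comparison(cohort.clinical, fusion)
for grp, (mean, se) in surv.mean_survival.items():
    print(f"\nmean survival, fusion-{grp}: {mean:.1f} +/- {se:.2f} months")
print(f"log-rank p = {surv.p_value:.3f}")
print("\nThe generator plants an MSI-H enrichment and a smaller tumour size "
      "in carriers but no survival difference; the MSI and size rows should "
      "trend low while the log-rank p stays unremarkable.")
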