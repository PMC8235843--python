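"""Diagnostic evaluation of the kinetic classifier against serum markers.

Runs the deterministic 24-patient fixture cohort through the diagnostics
stage: for each predictor (VAF_mean-change direction, AFP direction, DCP
direction, plus the marker-positive subgroups) it crosses the direction
call with the first radiologic response (mRECIST) and reports sensitivity,
specificity, PPV and NPV for predicting objective response (PR/CR), with a
decrease as the positive prediction. The kinetic classifier dominates both
serum markers; AFP falls in most patients regardless of response, so its
specificity collapses to 0.10.
"""

from ctdna_kinetics import evaluate_predictors, make_paper_fixture
from ctdna_kinetics.diagnostics import format_metric

cohort = make_paper_fixture()
blocks = evaluate_predictors(cohort)

header = f"{'predictor':16s} {'PD/SD/PRCR inc':>15s} {'PD/SD/PRCR dec':>15s}  spec  sens   ppv   npv"
print(header)
print("-" * len(header))
for name, block in blocks.items():
    table, metrics = block["table"], block["metrics"]
    inc = "/".join(str(table.row("increase")[g]) for g in ("PD", "SD", "PR/CR"))
    dec = "/".join(str(table.row("decrease")[g]) for g in ("PD", "SD", "PR/CR"))
    print(
        f"{name:16s} {inc:>15s} {dec:>15s}  "
        f"{format_metric(metrics.specificity):>4s}  "
        f"{format_metric(metrics.sensitivity):>4s}  "
        f"{format_metric(metrics.ppv):>4s}  "
        f"{format_metric(metrics.npv):>4s}"
    )
excluded = blocks["vaf_mean_change"]["table"].excluded_patients
print(f"\nexcluded from the VAF analysis (no ctDNA at either timepoint): {excluded}")
print("an en dash means the metric's denominator is zero (undefined, not 0)")
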