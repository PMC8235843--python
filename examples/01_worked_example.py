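"""The VAF_mean statistic on the canonical four-gene illustration.

A patient carries gene A at 11%, gene B at 4% and genes C and D undetected
at baseline; at week 4 the panel reads A=12%, B=4%, C=2%, D=0%. Gene D is
never seen, so it is excluded; gene C enters with a zero substituted at
baseline. The means are (11+4+0)/3 = 5 and (12+4+2)/3 = 6, so the change is
+1 and the patient lands in the kinetic "increase" group (a predicted
non-responder).
"""

from ctdna_kinetics import compute_change_and_direction, worked_example_patient
from ctdna_kinetics.kinetics import compute_vaf_mean, eligible_variants

patient = worked_example_patient()
table = eligible_variants(patient)
print("paired eligible-variant table:")
print(table.to_string(index=False))
print()
print(f"VAF_mean baseline : {compute_vaf_mean(table, 'baseline'):.1f} %")
print(f"VAF_mean week 4   : {compute_vaf_mean(table, 'week4'):.1f} %")
summary = compute_change_and_direction(patient)
print(f"VAF_mean-change   : {summary.vaf_mean_change:+.1f} percentage points")
print(f"direction group   : {summary.direction}  (change >= 0 predicts non-response)")
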