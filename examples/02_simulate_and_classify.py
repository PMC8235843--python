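"""Simulate a synthetic cohort and measure how well the kinetic direction
call recovers the true responder status.

The generator emulates a 24-patient two-timepoint panel study: lognormal
baseline VAFs censored at the 0.03% detection limit, responder VAFs scaled
down (factor 0.3) and non-responder VAFs up (factor 1.5) at week 4 with
multiplicative noise, occasional ~50%-VAF germline contaminants, and serum
markers that move mostly independently of response. At study size (n=24)
the recovered sensitivity/specificity bounce around; at n=500 both settle
above 0.9 under default noise.
"""

from ctdna_kinetics import SimulationConfig, classifier_recovery, simulate_cohort

for n in (24, 500):
    config = SimulationConfig(n_patients=n, seed=42)
    cohort, truth = simulate_cohort(config)
    recovery = classifier_recovery(cohort, truth)
    print(
        f"n={n:4d}: sensitivity={recovery['sensitivity']:.3f} "
        f"specificity={recovery['specificity']:.3f} "
        f"(classified {recovery['n_classified']}, "
        f"excluded {n - recovery['n_classified']})"
    )
print()
print("sensitivity = P(VAF_mean decrease | true responder);")
print("specificity = P(VAF_mean increase | true non-responder).")
print("Patients with no detectable ctDNA at either timepoint are excluded,")
print("not scored - the analysis never treats an undefined mean as zero.")
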