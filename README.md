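# ctdna-kinetics

Analysis pipeline for two-timepoint circulating tumor DNA (ctDNA) kinetics
from targeted-panel liquid biopsies, built for treatment-monitoring studies
in advanced solid tumors (the motivating setting is hepatocellular carcinoma
under multikinase-inhibitor therapy, profiled at baseline and after 4 weeks).

## The statistic

For each patient, let V be the set of somatic SNVs/indels detected at either
timepoint (a variant undetected at one timepoint contributes VAF 0 there; a
variant undetected at both is excluded). The per-patient summary is

```
VAF_mean(t)      = (1/|V|) * sum over v in V of VAF_v(t)          [percent]
VAF_mean-change  = VAF_mean(week 4) - VAF_mean(baseline)
```

The kinetic response classifier is the sign of the change: `< 0` (decrease)
predicts objective response, `>= 0` (increase) predicts non-response. A
patient with no detectable ctDNA at either timepoint has an *undefined*
VAF_mean and is excluded, never scored as zero. Variants are weighted
equally (per-variant aggregation); a per-gene mode (max VAF per gene) is
available behind a flag. Putative germline variants — VAF inside a
configurable band around 50% (default 40–60%, closed) at either timepoint —
are flagged and, by default, dropped as whole baseline/week-4 pairs.

Around this core the package provides:

- **variant I/O** — panel-report TSV and clinical CSV schemas, HGVS-based
  consequence classification (missense / nonsense / frameshift / in-frame /
  promoter / splice-site / synonymous), heatmap aggregation ("the greater
  VAF is shown"), and a minimal VCF 4.2 export;
- **kinetics** — VAF_mean, its change, direction calls, per-consequence-type
  changes, and detection of variants that are new or increased at week 4;
- **pathway classification** — baseline mutation status against GMT gene
  sets (WNT, PI3K/MTOR, cell cycle, chromatin remodeling, and TERT-promoter
  telomere maintenance);
- **diagnostics** — direction-by-mRECIST contingency tables with
  undefined-aware sensitivity/specificity/PPV/NPV, for the VAF classifier
  and for serum AFP/DCP (including marker-positive subgroups);
- **survival** — Kaplan–Meier curves, log-rank tests, Cox
  proportional-hazards fits (Breslow ties, Wald CIs) and Harrell-style
  bootstrap optimism correction of the concordance index;
- **therapy matching** — a two-step, fully local variant→drug procedure:
  pathogenicity filtering against annotation tables, then exact-first /
  class-fallback matching against an evidence-tiered knowledge base;
- **synthetic cohorts** — a generator with known ground truth emulating the
  study conditions (detection-limit censoring at 0.03% VAF, ~50%-VAF
  germline contaminants, responder-linked VAF decline, response-decoupled
  marker dynamics, exponential PFS with a configurable group hazard ratio).

## Worked example

```python
from ctdna_kinetics import compute_change_and_direction, worked_example_patient
from ctdna_kinetics.kinetics import compute_vaf_mean, eligible_variants

patient = worked_example_patient()   # A: 11->12, B: 4->4, C: 0->2, D: 0->0
table = eligible_variants(patient)   # D excluded; A, B, C paired with zeros
print(compute_vaf_mean(table, "baseline"))  # 5.0
print(compute_vaf_mean(table, "week4"))     # 6.0
summary = compute_change_and_direction(patient)
print(summary.vaf_mean_change, summary.direction)  # 1.0 increase
```

The means are (11+4+0)/3 = 5.0% and (12+4+2)/3 = 6.0%; the +1.0 change puts
the patient in the "increase" group, i.e. predicted non-responder. The
scripts in `examples/` walk through each capability the same way
(simulation and recovery, the diagnostic table, survival comparison,
therapy matching) and print the numbers they compute.

A thin CLI wraps the same functions:

```
ctdna-kin fixture --out-dir fx
ctdna-kin diagnostics --variants fx/variants.tsv --clinical fx/clinical.csv
ctdna-kin survival --variants fx/variants.tsv --clinical fx/clinical.csv --bootstrap 1000
```

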