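# Methods

## Model and procedure

The pipeline analyses a two-timepoint design: a targeted ctDNA panel at
baseline and again after 4 weeks of systemic treatment, with the first
radiologic evaluation (mRECIST) following at ~6 weeks. The per-patient
statistic, VAF_mean, is the arithmetic mean of variant allele frequencies
(percent) over the union of somatic SNVs/indels detected at either
timepoint. Three rules define the eligible set:

1. **Zero substitution** — a variant reported at one timepoint only enters
   the pair with VAF 0 at the other (disappearance and emergence both move
   the mean).
2. **Double-zero exclusion** — a variant at 0 at both timepoints carries no
   information and is excluded; adding such a variant never changes any
   output (asserted as a metamorphic property test).
3. **Undefined propagation** — a patient with no eligible variants has
   undefined VAF_mean (`None`, not 0) and is excluded from direction-based
   analyses; undefined values render as an en dash in reports and `null` in
   JSON.

VAF_mean-change = week-4 mean − baseline mean, on the same eligible set.
Direction: `< 0` → decrease (predicted responder); `>= 0` → increase; an
exact tie lands in the increase group so the two groups partition the
classified patients. Per-consequence-type changes recompute the difference
with the eligible set restricted to each type, so a single discordant
variant (e.g. a splice-site change rising while missense variants fall) is
visible.

### Aggregation unit

Variants are equally weighted (per-variant aggregation) by default; when a
gene carries several variants they all count individually. Because the
statistic is sometimes described per *gene*, a per-gene mode (maximum VAF
per gene per timepoint, mirroring the heatmap convention) is available via
`aggregation="gene"`. The two conventions disagree only for multi-variant
genes; the default follows the explicit equal-weighting convention for
panel-report SNVs and indels.

### Consequence classification

HGVS strings are classified by regular expressions, not transcript models:
protein-level `fs` → frameshift, trailing `*`/`Ter` → nonsense, same
residue → synonymous, del/ins/dup without `fs` → in-frame, otherwise
substitution → missense; cDNA-level `c.-N…` (upstream offset) → promoter,
intronic offsets with |offset| ≤ 2 → splice site (canonical dinucleotide),
larger offsets → other. Bare `ref>alt` pairs as printed in panel reports
classify by reading frame when lengths differ. When protein and cDNA
notations disagree, the most deleterious label wins under the fixed
precedence frameshift > nonsense > splice_site > promoter > in_frame >
missense > synonymous > other. Unparseable notation degrades to `other`
with a logged warning; a variant with no notation at all is an error.
Synonymous variants stay in VAF_mean by default (they are still tumor-derived
signal) and can be excluded by flag.

### Germline heuristic

Plasma genotyping sees heterozygous germline variants near 50% VAF, and
their allele balance does not move under treatment. SNV/indel calls inside
a closed band (default 40–60%) are flagged as putative germline; because
germline identity belongs to the variant rather than the timepoint, a flag
at either timepoint removes the whole baseline/week-4 pair from the
eligible set (default; `drop_germline=False` keeps flagged pairs). Band
edges are configurable — "close to 50%" is a heuristic, not a measurement,
and the synthetic generator deliberately plants contaminants at 45–55% so
the default band catches them with margin.

## Diagnostic evaluation

Each predictor (VAF direction, AFP direction, DCP direction — ties count as
increase for markers too) is crossed with response groups PD / SD / PR-CR
into a 2×3 table; objective response (PR or CR) is the positive condition
and a decrease the positive prediction, giving tp = decrease∧PR/CR,
fp = decrease∧(PD∪SD), tn = increase∧(PD∪SD), fn = increase∧PR/CR. All four
metrics are undefined (not 0) on a zero denominator. Marker subgroups
restrict to marker-positive patients (AFP ≥ 20 ng/mL, DCP ≥ 40 mAU/mL at
baseline). Display rounding is half-up to 2 decimals. A classified patient
with no recorded response is a loud error; silently dropping such patients
would bias the table.

## Survival analysis

Kaplan–Meier estimation and the k-sample log-rank test are delegated to
lifelines; the curve's median is the earliest time with survival ≤ 0.5
(inclusive — a curve touching exactly 0.5 has reached its median), undefined
when never reached. The Cox model uses statsmodels PHReg with the Breslow
tie approximation and Wald confidence intervals; concordance is Harrell's C
over usable pairs. Monotone-likelihood/separation problems are flagged on
the result (`converged=False`, enormous or non-finite standard errors)
rather than raised. Continuous covariates dichotomize at the median with
ties going to the "high" (≥ median) group. Penalized (lasso) fitting is out
of scope; `export_design_matrix` writes the time/event/covariate table for
external penalized fits.

The bootstrap optimism correction is Harrell-style: for each of B resamples
drawn with replacement, fit the model on the resample and record the gap
between its apparent concordance and the same fit scored on the original
data; corrected C = apparent C − mean gap, and Somers' D = 2C − 1.
Non-convergent resample fits are skipped and counted (> 20% skipped attaches
a warning). A single integer seed makes the whole procedure bit-reproducible.

## Therapy matching

A strictly local two-step procedure (no knowledge-base API calls):

1. **Pathogenicity filter.** A variant is kept iff at least one annotation
   source marks it pathogenic/likely-pathogenic at some scope AND no source
   marks it benign at exact-variant scope; exact verdicts override class
   verdicts, which override gene-level ones. Synonymous variants are
   auto-benign absent an exact override. Unannotated variants are
   "uncertain", dropped, and listed for review. The filter is idempotent.
2. **Knowledge-base match.** Exact variant entries are matched first; for a
   drug with no exact entry, class-scope entries whose predicate the
   variant satisfies apply (predicates: oncogenic_mutation = any variant
   that survived the filter, plus frameshift / nonsense / missense /
   promoter / splice_site / any_mutation), then gene-level entries. Each
   match is weighted by evidence tier × scope: exact matches score
   approved 100 / late trials 60 / early trials 40 / case-preclinical 20,
   class matches half, gene-level a quarter — any order-preserving scheme
   works; these values are configurable (`MatchWeights`). For the same
   (variant, drug, effect) only the highest-weight match is emitted;
   opposite effects for the same drug are both emitted with a conflict
   flag, since resistance is as actionable as sensitivity. Mixed source
   vocabularies for evidence levels (OncoKB LEVEL_1/3A/4, "Late trials",
   "Early trials", …) normalize onto the four tiers via a shipped mapping.
   Cancer-type restriction is off by default (cross-cancer repurposing is
   the interesting output) and available as a flag.

The shipped annotation and knowledge-base tables are small curated TSVs
covering the genes the fixture exercises; they are editable and replaceable
via `--annotations` / `--kb`.

## Synthetic cohorts

`simulate_cohort` draws, per patient: a Poisson(λ=6) variant count over a
32-gene panel subset; baseline VAFs lognormal on the log-percent scale with
μ = ln 0.28, σ = 1.9 — calibrated once so a 24-patient cohort's per-patient
VAF_mean has median ≈ 0.85% with maxima of order 10% — censored to 0 below
the 0.03% detection limit; week-4 VAFs = baseline × group factor
(responders 0.3, non-responders 1.5; responder fraction 14/24) × lognormal
noise (sd 0.25 on the log scale); an optional week-4-only emergent variant
(p = 0.15); a germline contaminant (p = 0.05) at 45–55% VAF at both
timepoints, emitted unflagged so the pipeline's own band filter must catch
it. Response labels follow true responder status (CR fraction 0.15 among
responders, PD fraction 0.4 among non-responders; label noise 0 by
default). AFP is positive (≥ 20 ng/mL) with probability 0.458 and falls in
92% of patients regardless of response; DCP rises in 79% — making the
markers deliberately poor classifiers. PFS is exponential with median 9.3
months in the decrease group and a hazard ratio of 8.4 for the increase
group, with independent exponential censoring (median 40 months); OS is
exponential (median 17.8 months) with no group effect. HGVS strings are
template-generated per consequence type so they round-trip through the
classifier.

The emitted cohort does not distinguish true absence from sub-limit signal
(as in the real assay); `GroundTruth` keeps the distinction, the true
responder flags, germline identities and group hazards for recovery tests.

**What passing tests do and do not show.** The generator reproduces the
*statistical skeleton* of a monitoring study — censoring, contamination,
group-linked kinetics, marker decoupling — not real tumor biology: no
clonal structure, no biologically realistic mutation spectrum, no
correlated VAFs within a patient, two timepoints only. Recovery results
(classifier sensitivity/specificity > 0.9 at n = 500 under default noise,
exactly 1.0 in the noiseless control; Cox log-HR within 3 SE of ln 8.4)
validate the pipeline's arithmetic and plumbing under known truth, not
clinical performance.

`make_paper_fixture` is a deterministic 24-patient cohort whose
direction-by-response margins reproduce all five published diagnostic
blocks simultaneously, with one no-ctDNA patient (exclusion path) and the
published emergent-variant rows in its four PD patients. Patient-level
values other than those margins and variant identities are synthetic.

## Numerical and design choices

- VAFs are percent everywhere (0.03 means 0.03%).
- Timepoint vocabulary is fixed to {baseline, week4}; richer longitudinal
  designs are out of scope.
- CNVs and fusions never enter VAF_mean (no allele frequency exists); CNV
  gene hits do not confer pathway-mutated status unless `include_cnv=True`.
- Pathway status uses baseline calls only; telomere maintenance requires a
  promoter-class TERT variant specifically.
- `detect_emergent` uses full-precision VAF comparison with
  `min_increase=0` (any strict rise counts); a noise-floor buffer is a
  caller decision.
- Emergent-variant reports and therapy matches are deterministically
  ordered (descending VAF / weight, ties alphabetical), so repeated runs
  are byte-identical.
- Problem sizes in the test suite and acceptance script (n = 500 cohorts,
  B = 200 bootstrap, 10 seeds) were chosen as the smallest sizes at which
  the asserted statistical properties are stable.

## Known limitations

- Consequence classification is notation-driven; it does not validate
  positions against transcript models and cannot classify a bare
  same-length coding substitution without a protein annotation.
- The germline band is a heuristic; somatic variants passing through the
  band are dropped (sacrificing signal for safety), and germline variants
  outside it are missed.
- The two printed TERT promoter rows aside, promoter detection assumes
  upstream ("c.-") notation.
- The knowledge-base fixture covers the genes the analyses exercise, not
  the full landscape of any public resource.
- Survival tooling covers single-endpoint right-censored comparisons; no
  competing risks, time-varying covariates, or multivariable selection.
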