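"""Variant-to-drug matching for variants that rose under treatment.

For the fixture cohort's progressive-disease patients: detect variants that
are new or increased at week 4, keep those with pathogenic/likely-pathogenic
annotations in the local tables (exact verdicts override class-level ones;
synonymous changes are auto-benign), then match against the local knowledge
base - exact variant entries first, falling back to variant-class and
gene-level entries - weighted by evidence tier and match specificity.
Resistance associations are reported alongside sensitivity ones.
"""

from ctdna_kinetics import make_paper_fixture
from ctdna_kinetics.matching import emergent_actionability_report, is_named_agent

report = emergent_actionability_report(make_paper_fixture())
pd_patients = [p for p in report if p.response == "PD"]
for patient in pd_patients:
    print(f"\n{patient.patient_id} (PD at first evaluation): "
          f"{len(patient.emergent)} emergent variants, "
          f"{len(patient.kept)} pathogenic after filtering")
    for match in patient.matches[:6]:
        flag = " [conflict]" if match.conflict else ""
        print(f"  {match.gene} {match.variant_label:10s} -> "
              f"{match.entry.drug:20s} {match.entry.effect:10s} "
              f"({match.match_type}, tier={match.entry.tier}, "
              f"weight={match.weight:.0f}){flag}")
    if len(patient.matches) > 6:
        print(f"  ... and {len(patient.matches) - 6} more")

named = [p.patient_id for p in pd_patients if p.has_named_agent_match]
print(f"\nPD patients matched to a named agent (not just a drug class): "
      f"{len(named)}/{len(pd_patients)} ({', '.join(named)})")
print("the remaining patient's matches are investigational drug-class entries only")
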