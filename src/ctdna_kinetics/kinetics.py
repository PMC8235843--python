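"""Two-timepoint VAF kinetics: VAF_mean, its change, and derived calls.

The per-patient statistic is the arithmetic mean of variant allele
frequencies (percent) over the variants detected at either timepoint — a
variant undetected at one timepoint contributes 0 there, and a variant
undetected at both timepoints is excluded entirely. The kinetic response
classifier is the sign of the change: ``week4 - baseline < 0`` is a
"decrease" (predicted responder), ``>= 0`` an "increase". A patient with no
eligible variants at either timepoint cannot be classified and is marked
"excluded".

Worked example: baseline A=11%, B=4%, C=0%, D=0%; week 4 A=12%, B=4%, C=2%,
D=0%. D is excluded; VAF_mean is (11+4+0)/3 = 5 at baseline and
(12+4+2)/3 = 6 at week 4; the change is +1 → "increase".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .variants import (
    DEFAULT_GERMLINE_BAND,
    MutationType,
    PatientRecord,
    ValidationError,
    VariantCall,
    VAF_CLASSES,
    is_germline,
)

DEFAULT_INCLUDE_CLASSES = frozenset({"SNV", "indel"})

DIRECTION_DECREASE = "decrease"
DIRECTION_INCREASE = "increase"
DIRECTION_EXCLUDED = "excluded"


@dataclass
class KineticsSummary:
    """Per-patient kinetics: VAF_mean at both timepoints and the change."""

    patient_id: str
    vaf_mean_baseline: Optional[float]
    vaf_mean_week4: Optional[float]
    vaf_mean_change: Optional[float]
    direction: str
    n_variants_used: int
    per_type_change: dict[MutationType, Optional[float]] = field(
        default_factory=dict
    )


@dataclass(frozen=True)
class EmergentVariant:
    """A variant newly detected, or with a VAF rise, at week 4."""

    patient_id: str
    gene: str
    variant_class: str
    hgvs_p: str
    hgvs_c: str
    status: str  # "novelly_detected" | "increased"
    vaf_baseline: float
    vaf_week4: float

    @property
    def label(self) -> str:
        return self.hgvs_p or self.hgvs_c or self.variant_class


def eligible_variants(
    patient: PatientRecord,
    include_classes: frozenset[str] = DEFAULT_INCLUDE_CLASSES,
    drop_germline: bool = True,
    germline_band: tuple[float, float] = DEFAULT_GERMLINE_BAND,
    include_synonymous: bool = True,
    aggregation: str = "variant",
) -> pd.DataFrame:
    """Build the paired VAF table the kinetics statistics operate on.

    Returns a DataFrame with one row per eligible variant and columns
    ``gene, variant_class, hgvs_p, hgvs_c, vaf_baseline, vaf_week4``:
    the union of variants reported at either timepoint, with 0 substituted
    where absent, minus variants at 0 at BOTH timepoints, minus classes
    outside ``include_classes``, minus germline-flagged calls (when
    ``drop_germline``). ``aggregation="gene"`` collapses to one row per gene
    with the maximum VAF at each timepoint.
    """
    if aggregation not in ("variant", "gene"):
        raise ValidationError(f"unknown aggregation {aggregation!r}")
    paired: dict[tuple, dict[str, float]] = {}
    meta: dict[tuple, VariantCall] = {}
    germline_keys: set[tuple] = set()
    for column, calls in (
        ("vaf_baseline", patient.baseline_calls),
        ("vaf_week4", patient.week4_calls),
    ):
        for call in calls:
            if call.variant_class not in include_classes:
                continue
            if call.variant_class not in VAF_CLASSES:
                continue  # CNVs/fusions carry no allele frequency
            if not include_synonymous and (call.hgvs_p or call.hgvs_c):
                if call.mutation_type() is MutationType.SYNONYMOUS:
                    continue
            key = call.variant_key
            # germline identity belongs to the variant, not the timepoint: a
            # call in the heterozygous band at EITHER timepoint marks the
            # whole baseline/week-4 pair
            if is_germline(call, germline_band):
                germline_keys.add(key)
            entry = paired.setdefault(key, {"vaf_baseline": 0.0, "vaf_week4": 0.0})
            entry[column] = max(entry[column], call.vaf)
            meta.setdefault(key, call)
    rows = []
    for key, entry in paired.items():
        if entry["vaf_baseline"] == 0.0 and entry["vaf_week4"] == 0.0:
            continue  # undetected at both timepoints: excluded
        if drop_germline and key in germline_keys:
            continue
        call = meta[key]
        rows.append(
            {
                "gene": call.gene,
                "variant_class": call.variant_class,
                "hgvs_p": call.hgvs_p,
                "hgvs_c": call.hgvs_c,
                "vaf_baseline": entry["vaf_baseline"],
                "vaf_week4": entry["vaf_week4"],
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene", "variant_class", "hgvs_p", "hgvs_c",
                 "vaf_baseline", "vaf_week4"],
    )
    if aggregation == "gene" and not table.empty:
        table = (
            table.groupby("gene", as_index=False, sort=False)
            .agg(
                variant_class=("variant_class", "first"),
                hgvs_p=("hgvs_p", "first"),
                hgvs_c=("hgvs_c", "first"),
                vaf_baseline=("vaf_baseline", "max"),
                vaf_week4=("vaf_week4", "max"),
            )
        )
    return table


def compute_vaf_mean(paired: pd.DataFrame, timepoint: str) -> Optional[float]:
    """Mean VAF (percent) over the eligible variants at one timepoint.

    Returns ``None`` for an empty table: a patient with no detectable ctDNA
    at either timepoint has no defined VAF_mean and is excluded from
    direction-based analyses rather than scored as 0.
    """
    column = {"baseline": "vaf_baseline", "week4": "vaf_week4"}.get(timepoint)
    if column is None:
        raise ValidationError(f"unknown timepoint {timepoint!r}")
    if paired.empty:
        return None
    return float(paired[column].mean())


def _classify_types(paired: pd.DataFrame) -> pd.Series:
    from .variants import classify_mutation_type

    def one(row):
        if not row["hgvs_p"] and not row["hgvs_c"]:
            return MutationType.OTHER
        return classify_mutation_type(row["hgvs_p"], row["hgvs_c"])

    return paired.apply(one, axis=1)


def compute_change_and_direction(
    patient: PatientRecord, **eligibility_options
) -> KineticsSummary:
    """VAF_mean at both timepoints, the change, and the direction call.

    The change is week-4 VAF_mean minus baseline VAF_mean over the SAME
    eligible-variant set. Direction: change < 0 → decrease; change >= 0 →
    increase (an exact tie lands in the increase group); no eligible
    variants → excluded. ``per_type_change`` recomputes the change with the
    eligible set restricted to each consequence type.
    """
    paired = eligible_variants(patient, **eligibility_options)
    per_type: dict[MutationType, Optional[float]] = {
        t: None for t in MutationType
    }
    if paired.empty:
        return KineticsSummary(
            patient_id=patient.patient_id,
            vaf_mean_baseline=None,
            vaf_mean_week4=None,
            vaf_mean_change=None,
            direction=DIRECTION_EXCLUDED,
            n_variants_used=0,
            per_type_change=per_type,
        )
    baseline = compute_vaf_mean(paired, "baseline")
    week4 = compute_vaf_mean(paired, "week4")
    change = week4 - baseline
    types = _classify_types(paired)
    for mutation_type in MutationType:
        subset = paired[types == mutation_type]
        if not subset.empty:
            per_type[mutation_type] = float(
                subset["vaf_week4"].mean() - subset["vaf_baseline"].mean()
            )
    return KineticsSummary(
        patient_id=patient.patient_id,
        vaf_mean_baseline=baseline,
        vaf_mean_week4=week4,
        vaf_mean_change=change,
        direction=DIRECTION_DECREASE if change < 0 else DIRECTION_INCREASE,
        n_variants_used=int(len(paired)),
        per_type_change=per_type,
    )


def detect_emergent(
    patient: PatientRecord,
    min_increase: float = 0.0,
    **eligibility_options,
) -> list[EmergentVariant]:
    """Variants newly detected at week 4 or with a VAF rise above baseline.

    A variant absent (or 0) at baseline and present at week 4 is
    ``novelly_detected``; one present at both timepoints with
    ``vaf_week4 - vaf_baseline > min_increase`` is ``increased``. Results
    are sorted by descending week-4 VAF (ties by gene then label, for a
    deterministic report).
    """
    if min_increase < 0:
        raise ValidationError("min_increase must be >= 0")
    paired = eligible_variants(patient, **eligibility_options)
    emergent = []
    for row in paired.to_dict("records"):
        baseline, week4 = row["vaf_baseline"], row["vaf_week4"]
        if baseline == 0.0 and week4 > 0.0:
            status = "novelly_detected"
        elif 0.0 < baseline and week4 - baseline > min_increase:
            status = "increased"
        else:
            continue
        emergent.append(
            EmergentVariant(
                patient_id=patient.patient_id,
                gene=row["gene"],
                variant_class=row["variant_class"],
                hgvs_p=row["hgvs_p"],
                hgvs_c=row["hgvs_c"],
                status=status,
                vaf_baseline=baseline,
                vaf_week4=week4,
            )
        )
    emergent.sort(key=lambda e: (-e.vaf_week4, e.gene, e.label))
    return emergent


def marker_direction(value_baseline: float, value_week4: float) -> str:
    """Direction of a serum-marker change (AFP/DCP), mirroring the VAF rule.

    Decrease iff the week-4 value is strictly below baseline; ties count as
    increase, the same convention as the VAF_mean-change >= 0 group.
    """
    if value_baseline < 0 or value_week4 < 0:
        raise ValidationError("marker values must be >= 0")
    return DIRECTION_DECREASE if value_week4 < value_baseline else DIRECTION_INCREASE


def summarize_cohort(cohort, **eligibility_options) -> list[KineticsSummary]:
    return [
        compute_change_and_direction(p, **eligibility_options) for p in cohort
    ]


def kinetics_frame(summaries: list[KineticsSummary]) -> pd.DataFrame:
    """One row per patient, with per-consequence-type change columns."""
    rows = []
    for s in summaries:
        row = {
            "patient_id": s.patient_id,
            "vaf_mean_baseline": s.vaf_mean_baseline,
            "vaf_mean_week4": s.vaf_mean_week4,
            "vaf_mean_change": s.vaf_mean_change,
            "direction": s.direction,
            "n_variants_used": s.n_variants_used,
        }
        for mutation_type in MutationType:
            row[f"change_{mutation_type.value}"] = s.per_type_change.get(
                mutation_type
            )
        rows.append(row)
    return pd.DataFrame(rows)


def emergent_frame(emergent: list[EmergentVariant]) -> pd.DataFrame:
    """Emergent-variant table mirroring the published report layout."""
    return pd.DataFrame(
        [
            {
                "gene": e.gene,
                "variant_type": e.variant_class,
                "mut_aa": e.hgvs_p,
                "mut_nt": e.hgvs_c,
                "patient_id": e.patient_id,
                "status": e.status,
                "vaf_baseline": e.vaf_baseline,
                "vaf_week4": e.vaf_week4,
            }
            for e in emergent
        ],
        columns=["gene", "variant_type", "mut_aa", "mut_nt", "patient_id",
                 "status", "vaf_baseline", "vaf_week4"],
    )
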