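"""Diagnostic evaluation of kinetic and serum-marker response classifiers.

Each predictor (VAF_mean-change direction, AFP direction, DCP direction) is
crossed with the first radiologic evaluation (mRECIST) into a 2x3 table
(increase/decrease x PD/SD/PR-CR). Objective response (PR or CR) is the
positive condition and a *decrease* the positive prediction, so:

    tp = decrease & PR/CR     fn = increase & PR/CR
    fp = decrease & (PD|SD)   tn = increase & (PD|SD)

Sensitivity, specificity, PPV and NPV are each undefined (``None``, rendered
as an en dash in reports) when their denominator is zero — e.g. NPV when no
patient was predicted negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional

from .kinetics import (
    DIRECTION_DECREASE,
    DIRECTION_EXCLUDED,
    DIRECTION_INCREASE,
    compute_change_and_direction,
    marker_direction,
)
from .variants import Cohort, PatientRecord, ValidationError

RESPONSE_GROUPS = ("PD", "SD", "PR/CR")
PREDICTORS = ("vaf_direction", "afp_direction", "dcp_direction")

#: Response categories counted as objective response.
DEFAULT_POSITIVE_RESPONSE = frozenset({"PR", "CR"})


@dataclass
class ResponseContingency:
    """2x3 direction-by-response counts plus the unclassifiable patients."""

    counts: dict[tuple[str, str], int]
    excluded_patients: list[str] = field(default_factory=list)
    predictor: str = ""

    def __post_init__(self) -> None:
        for key in self.counts:
            if self.counts[key] < 0:
                raise ValidationError(f"negative count for {key}")
        for direction in (DIRECTION_INCREASE, DIRECTION_DECREASE):
            for group in RESPONSE_GROUPS:
                self.counts.setdefault((direction, group), 0)

    def total(self) -> int:
        return sum(self.counts.values())

    def row(self, direction: str) -> dict[str, int]:
        return {g: self.counts[(direction, g)] for g in RESPONSE_GROUPS}


@dataclass
class DiagnosticResult:
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int


def _response_group(response: str) -> str:
    if response in ("PR", "CR"):
        return "PR/CR"
    if response in ("PD", "SD"):
        return response
    raise ValidationError(f"unknown response {response!r}")


def classify_direction(
    patient: PatientRecord, predictor: str, **kinetics_options
) -> str:
    """Direction call for one patient under one predictor.

    Marker predictors error on a missing marker value (the analysis cannot
    silently drop such a patient); the VAF predictor yields "excluded" when
    no ctDNA was detectable at either timepoint.
    """
    if predictor == "vaf_direction":
        return compute_change_and_direction(patient, **kinetics_options).direction
    if predictor == "afp_direction":
        if patient.afp_baseline is None or patient.afp_week4 is None:
            raise ValidationError(f"patient {patient.patient_id}: AFP missing")
        return marker_direction(patient.afp_baseline, patient.afp_week4)
    if predictor == "dcp_direction":
        if patient.dcp_baseline is None or patient.dcp_week4 is None:
            raise ValidationError(f"patient {patient.patient_id}: DCP missing")
        return marker_direction(patient.dcp_baseline, patient.dcp_week4)
    raise ValidationError(f"unknown predictor {predictor!r}")


def build_contingency(
    cohort: Cohort,
    predictor: str,
    subgroup: Optional[Callable[[PatientRecord], bool]] = None,
    **kinetics_options,
) -> ResponseContingency:
    """Cross a predictor's direction calls with mRECIST response groups.

    ``subgroup`` restricts the analysis (e.g. to AFP-positive patients,
    baseline >= 20 ng/mL). Patients whose VAF direction is "excluded" are
    listed, not counted. A classified patient without a recorded response is
    an error naming the patient.
    """
    counts: dict[tuple[str, str], int] = {}
    excluded: list[str] = []
    for patient in cohort:
        if subgroup is not None and not subgroup(patient):
            continue
        direction = classify_direction(patient, predictor, **kinetics_options)
        if direction == DIRECTION_EXCLUDED:
            excluded.append(patient.patient_id)
            continue
        if patient.response is None:
            raise ValidationError(
                f"patient {patient.patient_id} classified as {direction} "
                "but has no recorded response"
            )
        key = (direction, _response_group(patient.response))
        counts[key] = counts.get(key, 0) + 1
    return ResponseContingency(
        counts=counts, excluded_patients=excluded, predictor=predictor
    )


def afp_positive(threshold: float = 20.0) -> Callable[[PatientRecord], bool]:
    """Subgroup filter: baseline AFP >= threshold ng/mL."""
    return lambda p: p.afp_baseline is not None and p.afp_baseline >= threshold


def dcp_positive(threshold: float = 40.0) -> Callable[[PatientRecord], bool]:
    """Subgroup filter: baseline DCP >= threshold mAU/mL."""
    return lambda p: p.dcp_baseline is not None and p.dcp_baseline >= threshold


def diagnostic_metrics(
    table: ResponseContingency,
    positive_response: frozenset[str] = DEFAULT_POSITIVE_RESPONSE,
    positive_prediction: str = DIRECTION_DECREASE,
) -> DiagnosticResult:
    """Undefined-aware sensitivity/specificity/PPV/NPV from a 2x3 table."""
    if positive_prediction not in (DIRECTION_DECREASE, DIRECTION_INCREASE):
        raise ValidationError(f"unknown prediction {positive_prediction!r}")
    negative_prediction = (
        DIRECTION_INCREASE
        if positive_prediction == DIRECTION_DECREASE
        else DIRECTION_DECREASE
    )
    positive_groups = {"PR/CR"} if positive_response == DEFAULT_POSITIVE_RESPONSE \
        else {_response_group(r) for r in positive_response}
    tp = fp = tn = fn = 0
    for (direction, group), count in table.counts.items():
        condition_positive = group in positive_groups
        if direction == positive_prediction:
            if condition_positive:
                tp += count
            else:
                fp += count
        elif direction == negative_prediction:
            if condition_positive:
                fn += count
            else:
                tn += count
    def ratio(numerator: int, denominator: int) -> Optional[float]:
        return numerator / denominator if denominator else None

    return DiagnosticResult(
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def round_metric(value: Optional[float], digits: int = 2) -> Optional[float]:
    """Half-up rounding for display (0.675 -> 0.68, not banker's 0.67)."""
    if value is None:
        return None
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def format_metric(value: Optional[float], digits: int = 2) -> str:
    """Render a metric for the report; undefined prints as an en dash."""
    if value is None:
        return "–"
    return f"{round_metric(value, digits):.{digits}f}"


def evaluate_predictors(cohort: Cohort, **kinetics_options) -> dict[str, dict]:
    """The full diagnostic block: all predictors plus marker subgroups."""
    blocks = {}
    specs = [
        ("vaf_mean_change", "vaf_direction", None),
        ("afp_all_cases", "afp_direction", None),
        ("afp_ge20", "afp_direction", afp_positive(20.0)),
        ("dcp_all_cases", "dcp_direction", None),
        ("dcp_ge40", "dcp_direction", dcp_positive(40.0)),
    ]
    for name, predictor, subgroup in specs:
        table = build_contingency(
            cohort, predictor, subgroup=subgroup, **kinetics_options
        )
        metrics = diagnostic_metrics(table)
        blocks[name] = {"table": table, "metrics": metrics}
    return blocks
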