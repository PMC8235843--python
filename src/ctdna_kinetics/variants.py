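"""Data model for targeted-panel ctDNA variant reports.

A report row is one observed alteration (gene, variant class, HGVS strings,
VAF in percent or a plasma copy number) for one patient at one of the two
profiling timepoints (baseline, week 4 of treatment). Variant allele
frequencies are stored and reported in percent units throughout: ``vaf=0.03``
means 0.03%, the detection limit of the emulated assay.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

TIMEPOINTS = ("baseline", "week4")
VARIANT_CLASSES = ("SNV", "indel", "CNV", "fusion")

#: Variant classes that carry an allele frequency.
VAF_CLASSES = frozenset({"SNV", "indel"})


class MutationType(str, enum.Enum):
    """Functional consequence categories used for per-type kinetics."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    IN_FRAME = "in_frame"
    PROMOTER = "promoter"
    SPLICE_SITE = "splice_site"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Most-deleterious-first precedence when protein- and cDNA-level notations
#: suggest different consequences for the same call.
CONSEQUENCE_PRECEDENCE = (
    MutationType.FRAMESHIFT,
    MutationType.NONSENSE,
    MutationType.SPLICE_SITE,
    MutationType.PROMOTER,
    MutationType.IN_FRAME,
    MutationType.MISSENSE,
    MutationType.SYNONYMOUS,
    MutationType.OTHER,
)


class ValidationError(ValueError):
    """A record violates the schema contract."""


class ClassificationError(ValueError):
    """Raised when a variant carries no usable HGVS notation at all."""


class ConfigurationError(ValueError):
    """An option value is ill-formed (e.g. an inverted germline band)."""


@dataclass(frozen=True)
class VariantCall:
    """One observed alteration at one timepoint in one patient.

    ``vaf`` is required (and ``copy_number`` forbidden) for SNV/indel calls;
    the reverse holds for CNV calls. Fusions carry neither.
    """

    patient_id: str
    timepoint: str
    gene: str
    variant_class: str
    hgvs_p: str = ""
    hgvs_c: str = ""
    vaf: Optional[float] = None
    copy_number: Optional[float] = None
    germline_flag: bool = False

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValidationError("gene must be non-empty")
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(
                f"unknown timepoint {self.timepoint!r}; expected one of {TIMEPOINTS}"
            )
        if self.variant_class not in VARIANT_CLASSES:
            raise ValidationError(
                f"unknown variant_class {self.variant_class!r}; "
                f"expected one of {VARIANT_CLASSES}"
            )
        if self.variant_class in VAF_CLASSES:
            if self.vaf is None:
                raise ValidationError(
                    f"{self.variant_class} call {self.gene} requires a vaf"
                )
            if self.copy_number is not None:
                raise ValidationError("SNV/indel calls must not carry a copy_number")
        elif self.variant_class == "CNV":
            if self.copy_number is None:
                raise ValidationError(f"CNV call {self.gene} requires a copy_number")
            if self.vaf is not None:
                raise ValidationError("CNV calls must not carry a vaf")
            if self.copy_number <= 0:
                raise ValidationError("copy_number must be positive")
        if self.vaf is not None and not (0.0 <= self.vaf <= 100.0):
            raise ValidationError(f"vaf {self.vaf} outside [0, 100]")

    @property
    def variant_key(self) -> tuple[str, str, str, str]:
        """Identity used to pair the same alteration across timepoints."""
        return (self.gene, self.variant_class, self.hgvs_p, self.hgvs_c)

    @property
    def label(self) -> str:
        """Human-readable variant label (protein change if available)."""
        return self.hgvs_p or self.hgvs_c or self.variant_class

    def mutation_type(self) -> MutationType:
        return classify_mutation_type(self.hgvs_p, self.hgvs_c)


@dataclass
class PatientRecord:
    """Paired baseline/week-4 panels plus clinical covariates and endpoints.

    Serum markers: AFP in ng/mL, DCP in mAU/mL. ``response`` is the first
    radiologic evaluation (mRECIST): PD, SD, PR or CR; absent when not
    evaluated. Survival endpoints are in months with right censoring.
    """

    patient_id: str
    baseline_calls: list[VariantCall] = field(default_factory=list)
    week4_calls: list[VariantCall] = field(default_factory=list)
    afp_baseline: Optional[float] = None
    afp_week4: Optional[float] = None
    dcp_baseline: Optional[float] = None
    dcp_week4: Optional[float] = None
    tumor_size_baseline: Optional[float] = None
    tumor_size_week4: Optional[float] = None
    response: Optional[str] = None
    pfs_months: Optional[float] = None
    pfs_event: Optional[bool] = None
    os_months: Optional[float] = None
    os_event: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.response is not None and self.response not in ("PD", "SD", "PR", "CR"):
            raise ValidationError(f"unknown response {self.response!r}")
        for call in self.baseline_calls:
            self._check_call(call, "baseline")
        for call in self.week4_calls:
            self._check_call(call, "week4")
        for name in ("afp_baseline", "afp_week4", "dcp_baseline", "dcp_week4",
                     "tumor_size_baseline", "tumor_size_week4"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(f"{name} must be >= 0, got {value}")

    def _check_call(self, call: VariantCall, timepoint: str) -> None:
        if call.patient_id != self.patient_id:
            raise ValidationError(
                f"call for {call.patient_id!r} attached to patient {self.patient_id!r}"
            )
        if call.timepoint != timepoint:
            raise ValidationError(
                f"{timepoint} panel of {self.patient_id} holds a "
                f"{call.timepoint} call"
            )

    def calls(self, timepoint: str) -> list[VariantCall]:
        if timepoint == "baseline":
            return self.baseline_calls
        if timepoint == "week4":
            return self.week4_calls
        raise ValidationError(f"unknown timepoint {timepoint!r}")


@dataclass
class Cohort:
    """A set of patients profiled at both timepoints on the same panel."""

    patients: list[PatientRecord]
    detection_limit_vaf: float = 0.03

    def __post_init__(self) -> None:
        if self.detection_limit_vaf <= 0:
            raise ValidationError("detection_limit_vaf must be > 0")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient_ids: {dupes}")

    def __iter__(self):
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def get(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)


# --- HGVS-based consequence classification ---------------------------------

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Sec": "U", "Ter": "*",
}

_P_SUB_RE = re.compile(r"^([A-Z\*])(\d+)([A-Z\*=])$")
_C_PROMOTER_RE = re.compile(r"^-\d+")
_C_INTRONIC_RE = re.compile(r"^\*?\d+([+-]\d+)")
_C_REF_ALT_RE = re.compile(r"^([ACGT]+)>([ACGT]+)$")


def _normalize_protein(hgvs_p: str) -> str:
    s = hgvs_p.strip()
    if s.lower().startswith("p."):
        s = s[2:]
    s = s.strip("()").replace(" ", "")
    # three-letter residue codes -> one-letter, "Ter" -> "*"
    for three, one in _AA3_TO_1.items():
        s = s.replace(three, one)
    return s


def _normalize_cdna(hgvs_c: str) -> str:
    s = hgvs_c.strip().replace(" ", "")
    if s.lower().startswith("c."):
        s = s[2:]
    return s


def _classify_protein(hgvs_p: str) -> Optional[MutationType]:
    s = _normalize_protein(hgvs_p)
    if not s:
        return None
    low = s.lower()
    if "fs" in low:
        return MutationType.FRAMESHIFT
    if any(tok in low for tok in ("delins", "del", "ins", "dup")):
        return MutationType.IN_FRAME
    if low.endswith("ext"):
        return MutationType.OTHER
    m = _P_SUB_RE.match(s)
    if m:
        ref, _, alt = m.groups()
        if alt == "*":
            return MutationType.NONSENSE
        if alt == "=" or ref == alt:
            return MutationType.SYNONYMOUS
        return MutationType.MISSENSE
    logger.warning("unparseable protein notation %r; classified as other", hgvs_p)
    return MutationType.OTHER


def _classify_cdna(hgvs_c: str) -> Optional[MutationType]:
    s = _normalize_cdna(hgvs_c)
    if not s:
        return None
    if _C_PROMOTER_RE.match(s):
        return MutationType.PROMOTER
    m = _C_INTRONIC_RE.match(s)
    if m:
        offset = int(m.group(1))
        if offset != 0:
            if abs(offset) <= 2:
                return MutationType.SPLICE_SITE
            return MutationType.OTHER
    m = _C_REF_ALT_RE.match(s)
    if m:
        # Panel reports sometimes print bare ref>alt pairs (VCF style) in the
        # nucleotide column. A length change classifies by reading frame; a
        # same-length substitution is uninformative at the cDNA level.
        ref, alt = m.groups()
        diff = abs(len(alt) - len(ref))
        if diff:
            return (MutationType.FRAMESHIFT if diff % 3
                    else MutationType.IN_FRAME)
        return None
    if re.match(r"^\d+", s):
        # plain coding-region change; consequence not inferable from cDNA alone
        return None
    logger.warning("unparseable cDNA notation %r; classified as other", hgvs_c)
    return MutationType.OTHER


def classify_mutation_type(hgvs_p: str = "", hgvs_c: str = "") -> MutationType:
    """Assign a single consequence label from HGVS notation.

    Protein- and cDNA-level notations are classified independently and the
    most deleterious candidate wins under the fixed precedence
    frameshift > nonsense > splice_site > promoter > in_frame > missense >
    synonymous > other. Unparseable notation degrades to ``other`` with a
    logged warning; two empty strings raise :class:`ClassificationError`.
    """
    if not hgvs_p.strip() and not hgvs_c.strip():
        raise ClassificationError("variant carries neither hgvs_p nor hgvs_c")
    candidates = set()
    label = _classify_protein(hgvs_p)
    if label is not None:
        candidates.add(label)
    label = _classify_cdna(hgvs_c)
    if label is not None:
        candidates.add(label)
    if not candidates:
        return MutationType.OTHER
    for label in CONSEQUENCE_PRECEDENCE:
        if label in candidates:
            return label
    return MutationType.OTHER  # pragma: no cover


# --- Germline heuristic and report aggregation ------------------------------

DEFAULT_GERMLINE_BAND = (40.0, 60.0)


def flag_putative_germline(
    call: VariantCall, band: tuple[float, float] = DEFAULT_GERMLINE_BAND
) -> bool:
    """Flag an SNV/indel whose VAF sits in the heterozygous-germline band.

    Inherited variants appear in plasma near 50% VAF; calls inside the closed
    ``band`` (default 40-60%) are flagged as putative germline. This only
    flags — dropping flagged calls is a separate, configurable filter step.
    """
    lo, hi = band
    if lo >= hi:
        raise ConfigurationError(f"germline band ill-ordered: [{lo}, {hi}]")
    if call.variant_class not in VAF_CLASSES or call.vaf is None:
        raise ValidationError(
            "germline flagging applies to SNV/indel calls with a vaf"
        )
    return lo <= call.vaf <= hi

def is_germline(
    call: VariantCall, band: tuple[float, float] = DEFAULT_GERMLINE_BAND
) -> bool:
    """True when a call is flagged germline upstream or falls in ``band``."""
    if call.germline_flag:
        return True
    if call.variant_class in VAF_CLASSES and call.vaf is not None:
        return flag_putative_germline(call, band)
    return False


def heatmap_value(calls: Sequence[VariantCall]) -> Optional[float]:
    """Collapse same-gene/same-timepoint calls to one displayable value.

    When a gene carries multiple variants in the same patient, the greater
    VAF (SNV/indel) or greater plasma copy number (CNV) is shown. Empty input
    yields ``None`` (rendered as blank/0 in a heatmap), not an error.
    """
    if not calls:
        return None
    keys = {(c.patient_id, c.gene, c.timepoint) for c in calls}
    if len(keys) > 1:
        raise ValidationError("calls must share patient, gene and timepoint")
    classes = {c.variant_class in VAF_CLASSES for c in calls}
    if len(classes) > 1:
        raise ValidationError("cannot mix VAF-bearing and CNV calls")
    if calls[0].variant_class in VAF_CLASSES:
        return max(c.vaf for c in calls)
    return max(c.copy_number for c in calls)


def iter_calls(patients: Iterable[PatientRecord]) -> Iterable[VariantCall]:
    for patient in patients:
        yield from patient.baseline_calls
        yield from patient.week4_calls
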