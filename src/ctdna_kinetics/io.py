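"""Readers and writers for the panel-report TSV, clinical CSV and VCF stub.

Variant TSV schema (tab-separated, UTF-8, header row)::

    patient_id  timepoint  gene  variant_class  hgvs_c  hgvs_p  vaf_percent
    copy_number  [germline_flag]

Clinical CSV schema::

    patient_id, response, afp_baseline, afp_week4, dcp_baseline, dcp_week4,
    tumor_size_baseline_mm, tumor_size_week4_mm, pfs_months, pfs_event,
    os_months, os_event

Empty cells denote inapplicable/absent fields. Rows with a VAF of exactly 0
are retained: a reported-but-undetected variant participates in the paired
kinetics table (zero at one timepoint), unlike a variant never reported.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .variants import (
    Cohort,
    PatientRecord,
    ValidationError,
    VariantCall,
    VAF_CLASSES,
    VARIANT_CLASSES,
)

VARIANT_COLUMNS = (
    "patient_id", "timepoint", "gene", "variant_class",
    "hgvs_c", "hgvs_p", "vaf_percent", "copy_number",
)
MANDATORY_VARIANT_COLUMNS = ("patient_id", "timepoint", "gene", "variant_class")

CLINICAL_COLUMNS = (
    "patient_id", "response",
    "afp_baseline", "afp_week4", "dcp_baseline", "dcp_week4",
    "tumor_size_baseline_mm", "tumor_size_week4_mm",
    "pfs_months", "pfs_event", "os_months", "os_event",
)


class SchemaError(ValueError):
    """A mandatory column is missing or misnamed."""


def _is_blank(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def _opt_float(value, column: str, row: int) -> Optional[float]:
    if _is_blank(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"row {row}: column {column!r} not parseable as number: {value!r}"
        ) from None


def read_variant_table(
    path: str | Path, schema: Optional[Mapping[str, str]] = None
) -> list[VariantCall]:
    """Read a panel-report TSV into :class:`VariantCall` records.

    ``schema`` maps canonical column names to the names used in the file
    (e.g. ``{"vaf_percent": "VAF%"}``). Input row order is preserved; row
    numbers in error messages are 1-based data rows.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (schema or {}).items()}
    frame = frame.rename(columns=rename)
    for column in MANDATORY_VARIANT_COLUMNS:
        if column not in frame.columns:
            raise SchemaError(f"missing mandatory column {column!r}")
    calls: list[VariantCall] = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        variant_class = str(row["variant_class"]).strip()
        if variant_class not in VARIANT_CLASSES:
            raise ValidationError(
                f"row {i}: unknown variant_class {variant_class!r}"
            )
        vaf = _opt_float(row.get("vaf_percent"), "vaf_percent", i)
        if variant_class in VAF_CLASSES and vaf is None:
            raise ValidationError(f"row {i}: {variant_class} requires vaf_percent")
        if vaf is not None and not (0.0 <= vaf <= 100.0):
            raise ValidationError(f"row {i}: vaf_percent {vaf} outside [0, 100]")
        germline = str(row.get("germline_flag", "")).strip().lower() in (
            "1", "true", "yes",
        )
        try:
            calls.append(
                VariantCall(
                    patient_id=str(row["patient_id"]).strip(),
                    timepoint=str(row["timepoint"]).strip(),
                    gene=str(row["gene"]).strip(),
                    variant_class=variant_class,
                    hgvs_c=str(row.get("hgvs_c", "")).strip(),
                    hgvs_p=str(row.get("hgvs_p", "")).strip(),
                    vaf=vaf,
                    copy_number=_opt_float(row.get("copy_number"), "copy_number", i),
                    germline_flag=germline,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
    return calls


def write_variant_table(calls: Sequence[VariantCall], path: str | Path) -> None:
    rows = [
        {
            "patient_id": c.patient_id,
            "timepoint": c.timepoint,
            "gene": c.gene,
            "variant_class": c.variant_class,
            "hgvs_c": c.hgvs_c,
            "hgvs_p": c.hgvs_p,
            "vaf_percent": "" if c.vaf is None else repr(float(c.vaf)),
            "copy_number": "" if c.copy_number is None else repr(float(c.copy_number)),
            "germline_flag": "true" if c.germline_flag else "",
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS + ("germline_flag",)).to_csv(
        path, sep="\t", index=False
    )


def _opt_bool(value, column: str, row: int) -> Optional[bool]:
    if _is_blank(value):
        return None
    text = str(value).strip().lower()
    if text in ("1", "true", "yes"):
        return True
    if text in ("0", "false", "no"):
        return False
    raise ValidationError(f"row {row}: column {column!r} not a boolean: {value!r}")


def read_clinical_table(path: str | Path) -> list[PatientRecord]:
    """Read the clinical CSV into bare :class:`PatientRecord` shells."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "patient_id" not in frame.columns:
        raise SchemaError("missing mandatory column 'patient_id'")
    records = []
    for i, row in enumerate(frame.to_dict("records"), start=1):
        response = str(row.get("response", "")).strip() or None
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]).strip(),
                response=response,
                afp_baseline=_opt_float(row.get("afp_baseline"), "afp_baseline", i),
                afp_week4=_opt_float(row.get("afp_week4"), "afp_week4", i),
                dcp_baseline=_opt_float(row.get("dcp_baseline"), "dcp_baseline", i),
                dcp_week4=_opt_float(row.get("dcp_week4"), "dcp_week4", i),
                tumor_size_baseline=_opt_float(
                    row.get("tumor_size_baseline_mm"), "tumor_size_baseline_mm", i
                ),
                tumor_size_week4=_opt_float(
                    row.get("tumor_size_week4_mm"), "tumor_size_week4_mm", i
                ),
                pfs_months=_opt_float(row.get("pfs_months"), "pfs_months", i),
                pfs_event=_opt_bool(row.get("pfs_event"), "pfs_event", i),
                os_months=_opt_float(row.get("os_months"), "os_months", i),
                os_event=_opt_bool(row.get("os_event"), "os_event", i),
            )
        )
    return records


def write_clinical_table(patients: Sequence[PatientRecord], path: str | Path) -> None:
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "true" if v else "false"
        return v

    rows = [
        {
            "patient_id": p.patient_id,
            "response": fmt(p.response),
            "afp_baseline": fmt(p.afp_baseline),
            "afp_week4": fmt(p.afp_week4),
            "dcp_baseline": fmt(p.dcp_baseline),
            "dcp_week4": fmt(p.dcp_week4),
            "tumor_size_baseline_mm": fmt(p.tumor_size_baseline),
            "tumor_size_week4_mm": fmt(p.tumor_size_week4),
            "pfs_months": fmt(p.pfs_months),
            "pfs_event": fmt(p.pfs_event),
            "os_months": fmt(p.os_months),
            "os_event": fmt(p.os_event),
        }
        for p in patients
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def assemble_cohort(
    calls: Sequence[VariantCall],
    clinical: Sequence[PatientRecord],
    detection_limit_vaf: float = 0.03,
) -> Cohort:
    """Attach variant calls to their clinical records by patient id.

    Patients present only in the variant table get a bare clinical shell;
    patients with no calls keep empty panels (they may still be analysable
    for markers and survival).
    """
    by_id = {p.patient_id: p for p in clinical}
    order = [p.patient_id for p in clinical]
    for call in calls:
        patient = by_id.get(call.patient_id)
        if patient is None:
            patient = PatientRecord(patient_id=call.patient_id)
            by_id[call.patient_id] = patient
            order.append(call.patient_id)
        patient.calls(call.timepoint).append(call)
    return Cohort(
        patients=[by_id[i] for i in order],
        detection_limit_vaf=detection_limit_vaf,
    )


def load_cohort(
    variant_path: str | Path,
    clinical_path: Optional[str | Path] = None,
    detection_limit_vaf: float = 0.03,
    schema: Optional[Mapping[str, str]] = None,
) -> Cohort:
    calls = read_variant_table(variant_path, schema=schema)
    clinical = read_clinical_table(clinical_path) if clinical_path else []
    return assemble_cohort(calls, clinical, detection_limit_vaf)


# --- VCF stub export ---------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=ctdna-kinetics
##INFO=<ID=GENE,Number=1,Type=String,Description="HGNC gene symbol">
##INFO=<ID=CLASS,Number=1,Type=String,Description="Variant class (SNV/indel/CNV/fusion)">
##INFO=<ID=HGVSC,Number=1,Type=String,Description="cDNA-level HGVS change">
##INFO=<ID=HGVSP,Number=1,Type=String,Description="Protein-level HGVS change">
##INFO=<ID=VAF_PCT,Number=1,Type=Float,Description="Variant allele frequency in percent">
##INFO=<ID=CN,Number=1,Type=Float,Description="Plasma copy number (CNV only)">
##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">
##INFO=<ID=TIMEPOINT,Number=1,Type=String,Description="Profiling timepoint">
##ALT=<ID=CNV,Description="Copy number variant">
##ALT=<ID=FUS,Description="Gene fusion">
##contig=<ID=chrUn>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _info_escape(value: str) -> str:
    return (
        value.replace("%", "%25").replace(";", "%3B")
        .replace("=", "%3D").replace(",", "%2C").replace(" ", "%20")
    )


def _info_unescape(value: str) -> str:
    return (
        value.replace("%20", " ").replace("%2C", ",").replace("%3D", "=")
        .replace("%3B", ";").replace("%25", "%")
    )


def write_vcf_stub(calls: Sequence[VariantCall], path: str | Path) -> None:
    """Export calls as a minimal VCF 4.2 without genomic coordinates.

    The panel report carries no chromosome/position, so records sit on a
    placeholder contig with a running position; all substance lives in the
    INFO keys (GENE/CLASS/HGVSC/HGVSP/VAF_PCT/CN) and round-trips through
    :func:`read_vcf_stub`. CNVs and fusions use symbolic ALT alleles.
    """
    if not calls:
        raise ValidationError("write_vcf_stub requires at least one call")
    lines = [_VCF_HEADER]
    for pos, call in enumerate(calls, start=1):
        ref, alt = "N", "<CNV>" if call.variant_class == "CNV" else None
        if call.variant_class == "fusion":
            alt = "<FUS>"
        if alt is None:
            nt = call.hgvs_c.replace(" ", "")
            m = None
            if ">" in nt:
                parts = nt.split(">")
                tail = parts[0][-1:] if parts[0] else ""
                if tail in "ACGT" and parts[1] and all(
                    c in "ACGT" for c in parts[1]
                ):
                    left = parts[0]
                    i = len(left)
                    while i > 0 and left[i - 1] in "ACGT":
                        i -= 1
                    m = (left[i:], parts[1])
            ref, alt = m if m else ("N", "<ALT>")
        info = [
            f"GENE={_info_escape(call.gene)}",
            f"CLASS={call.variant_class}",
        ]
        if call.hgvs_c:
            info.append(f"HGVSC={_info_escape(call.hgvs_c)}")
        if call.hgvs_p:
            info.append(f"HGVSP={_info_escape(call.hgvs_p)}")
        if call.vaf is not None:
            info.append(f"VAF_PCT={call.vaf:.4f}")
        if call.copy_number is not None:
            info.append(f"CN={call.copy_number:.4f}")
        info.append(f"PATIENT={_info_escape(call.patient_id)}")
        info.append(f"TIMEPOINT={call.timepoint}")
        lines.append(
            f"chrUn\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{';'.join(info)}\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf_stub(path: str | Path) -> list[VariantCall]:
    """Read back the INFO fields of a :func:`write_vcf_stub` export."""
    calls = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        info = dict(
            item.split("=", 1) for item in fields[7].split(";") if "=" in item
        )
        calls.append(
            VariantCall(
                patient_id=_info_unescape(info.get("PATIENT", "")),
                timepoint=info.get("TIMEPOINT", "baseline"),
                gene=_info_unescape(info.get("GENE", "")),
                variant_class=info.get("CLASS", "SNV"),
                hgvs_c=_info_unescape(info.get("HGVSC", "")),
                hgvs_p=_info_unescape(info.get("HGVSP", "")),
                vaf=float(info["VAF_PCT"]) if "VAF_PCT" in info else None,
                copy_number=float(info["CN"]) if "CN" in info else None,
            )
        )
    return calls
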