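"""Baseline pathway-mutation status from GMT gene sets.

Patients are classified by whether the baseline panel carries at least one
eligible somatic SNV/indel in a member gene of each pathway gene set (WNT,
PI3K/MTOR, cell-cycle control, chromatin remodeling). Telomere maintenance
is special-cased: it requires a promoter-class variant in TERT, since the
panel's telomere signal is the TERT promoter hotspot region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import pandas as pd

from .variants import (
    DEFAULT_GERMLINE_BAND,
    Cohort,
    MutationType,
    PatientRecord,
    ValidationError,
    is_germline,
)

#: Pathway name that additionally requires a TERT promoter-class variant.
TELOMERE_PATHWAY = "TELOMERE_MAINTENANCE"


class GMTParseError(ValueError):
    """Malformed GMT line (fewer than 3 tab-separated fields)."""


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset[str]]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")


@dataclass(frozen=True)
class PathwayCall:
    patient_id: str
    pathway: str
    mutated: bool
    supporting_variants: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mutated != bool(self.supporting_variants):
            raise ValidationError(
                "mutated flag must match presence of supporting variants"
            )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line as name, description, genes...

    Duplicate genes within a line are deduplicated; a duplicate set name is
    an error (two sources for the same pathway belong on one merged line).
    """
    sets: dict[str, frozenset[str]] = {}
    provenance: dict[str, str] = {}
    for number, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise GMTParseError(
                f"{path}:{number}: expected >= 3 tab-separated fields, "
                f"got {len(fields)}"
            )
        name, description = fields[0], fields[1]
        if name in sets:
            raise GMTParseError(f"{path}:{number}: duplicate set name {name!r}")
        genes = frozenset(g.strip() for g in fields[2:] if g.strip())
        sets[name] = genes
        provenance[name] = description
    return GeneSetCollection(sets=sets, provenance=provenance)


def default_gene_sets() -> GeneSetCollection:
    """The curated HCC pathway sets shipped with the package.

    Small editable lists covering the panel genes observed per pathway; they
    stand in for the full GO/Reactome sets, which are not redistributed.
    """
    with resources.as_file(
        resources.files("ctdna_kinetics.data").joinpath("hcc_pathways.gmt")
    ) as path:
        return read_gmt(path)


def classify_patient_pathways(
    patient: PatientRecord,
    collection: GeneSetCollection,
    timepoint: str = "baseline",
    include_cnv: bool = False,
    drop_germline: bool = True,
    germline_band: tuple[float, float] = DEFAULT_GERMLINE_BAND,
) -> list[PathwayCall]:
    """Pathway-mutated flags for one patient from the baseline panel.

    A pathway is mutated iff >= 1 eligible (SNV/indel, non-germline, VAF > 0)
    variant's gene belongs to the set; CNV-level hits count only when
    ``include_cnv``. A patient may be positive for several pathways. Only the
    requested timepoint's panel is consulted.
    """
    if timepoint not in ("baseline", "week4"):
        raise ValidationError(f"unknown timepoint {timepoint!r}")
    calls = patient.calls(timepoint)
    results = []
    for pathway, genes in collection.sets.items():
        supporting = []
        for call in calls:
            if call.gene not in genes:
                continue
            if call.variant_class in ("SNV", "indel"):
                if call.vaf is None or call.vaf <= 0:
                    continue
                if drop_germline and is_germline(call, germline_band):
                    continue
                if pathway == TELOMERE_PATHWAY:
                    if call.gene != "TERT":
                        continue
                    if not (call.hgvs_p or call.hgvs_c):
                        continue
                    if call.mutation_type() is not MutationType.PROMOTER:
                        continue
            elif call.variant_class == "CNV" and include_cnv:
                if pathway == TELOMERE_PATHWAY:
                    continue
            else:
                continue
            supporting.append(f"{call.gene}:{call.label}")
        results.append(
            PathwayCall(
                patient_id=patient.patient_id,
                pathway=pathway,
                mutated=bool(supporting),
                supporting_variants=tuple(supporting),
            )
        )
    return results


def pathway_matrix(
    cohort: Cohort,
    collection: Optional[GeneSetCollection] = None,
    **options,
) -> pd.DataFrame:
    """Patient x pathway boolean matrix over the whole cohort."""
    collection = collection or default_gene_sets()
    rows = {}
    for patient in cohort:
        calls = classify_patient_pathways(patient, collection, **options)
        rows[patient.patient_id] = {c.pathway: c.mutated for c in calls}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("patient_id")
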