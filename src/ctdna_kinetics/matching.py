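"""Evidence-weighted matching of observed variants to candidate therapies.

Two steps, run against local tables only (no live knowledge-base queries):

1. Pathogenicity filtering — keep a variant iff at least one annotation
   source calls it pathogenic/likely pathogenic at some scope AND no source
   calls it benign at exact-variant scope (an exact benign verdict overrides
   any class- or gene-level pathogenic one). Synonymous variants are
   auto-benign unless an exact annotation says otherwise; unannotated
   variants are "uncertain" and are dropped but listed for review.

2. Knowledge-base matching — exact variant matches first, then class-scope
   entries whose predicate the variant satisfies, then gene-level entries,
   each weighted by (match scope, evidence tier). Responsive and resistant
   associations are both reported: resistance is actionable information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .kinetics import EmergentVariant, detect_emergent
from .variants import Cohort, MutationType, ValidationError, VariantCall

SCOPES = ("exact_variant", "variant_class", "gene_level")
VERDICTS = ("pathogenic", "likely_pathogenic", "benign", "uncertain")
EFFECTS = ("responsive", "resistant")
TIERS = ("approved", "late_trials", "early_trials", "case_preclinical")

#: Class predicates a knowledge-base or annotation row may use.
CLASS_PREDICATES = (
    "oncogenic_mutation", "frameshift", "nonsense", "missense",
    "promoter", "splice_site", "any_mutation",
)

#: Source evidence-level vocabulary -> the four tiers. OncoKB numeric levels:
#: 1/2 approved-or-standard-care, 3A late trials, 4 preclinical/biological.
TIER_ALIASES = {
    "approved": "approved",
    "level_1": "approved",
    "level_2": "approved",
    "level_3a": "late_trials",
    "level_3b": "late_trials",
    "late_trials": "late_trials",
    "late trials": "late_trials",
    "early_trials": "early_trials",
    "early trials": "early_trials",
    "level_4": "case_preclinical",
    "case_preclinical": "case_preclinical",
    "case/preclinical": "case_preclinical",
    "preclinical": "case_preclinical",
    "case report": "case_preclinical",
}

#: Weight of an exact-scope match per evidence tier; class-scope matches get
#: 50% of the exact weight and gene-level 25%. Any strictly order-preserving
#: scheme works; these values are configurable via ``MatchWeights``.
DEFAULT_EXACT_WEIGHTS = {
    "approved": 100.0,
    "late_trials": 60.0,
    "early_trials": 40.0,
    "case_preclinical": 20.0,
}
SCOPE_FACTORS = {"exact_variant": 1.0, "variant_class": 0.5, "gene_level": 0.25}


@dataclass(frozen=True)
class MatchWeights:
    exact_weights: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_EXACT_WEIGHTS.items()
    )
    scope_factors: tuple[tuple[str, float], ...] = tuple(SCOPE_FACTORS.items())

    def weight(self, scope: str, tier: str) -> float:
        return dict(self.exact_weights)[tier] * dict(self.scope_factors)[scope]


def normalize_tier(label: str) -> str:
    key = label.strip().lower()
    if key in TIER_ALIASES:
        return TIER_ALIASES[key]
    if key in TIERS:
        return key
    raise ValidationError(f"unknown evidence-level label {label!r}")


@dataclass(frozen=True)
class PathogenicityAnnotation:
    gene: str
    scope: str
    pattern: str  # concrete HGVS string (exact) or a class predicate
    verdict: str
    source: str

    def __post_init__(self) -> None:
        if self.scope not in SCOPES:
            raise ValidationError(f"unknown scope {self.scope!r}")
        if self.verdict not in VERDICTS:
            raise ValidationError(f"unknown verdict {self.verdict!r}")
        if self.scope == "exact_variant" and not self.pattern:
            raise ValidationError("exact_variant scope requires a concrete pattern")


@dataclass(frozen=True)
class KnowledgeBaseEntry:
    gene: str
    scope: str
    pattern: str
    drug: str
    effect: str
    tier: str
    source: str
    reference: str = ""
    cancer_type: str = ""

    def __post_init__(self) -> None:
        if not self.drug:
            raise ValidationError("knowledge-base entry requires a drug")
        if self.scope not in SCOPES:
            raise ValidationError(f"unknown scope {self.scope!r}")
        if self.effect not in EFFECTS:
            raise ValidationError(f"unknown effect {self.effect!r}")
        if self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}")


@dataclass(frozen=True)
class FilteredVariant:
    variant: VariantCall
    verdict: str
    sources: tuple[str, ...]


@dataclass(frozen=True)
class TherapyMatch:
    patient_id: str
    gene: str
    variant_label: str
    entry: KnowledgeBaseEntry
    match_type: str  # "exact" | "class" | "gene"
    weight: float
    conflict: bool = False


# --- table loading -----------------------------------------------------------

def _load_rows(path: str | Path, columns: Sequence[str]) -> list[dict]:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                        comment="#").fillna("")
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return frame.to_dict("records")


def read_annotations(path: str | Path) -> list[PathogenicityAnnotation]:
    rows = _load_rows(path, ("gene", "scope", "pattern", "verdict", "source"))
    annotations = []
    for i, row in enumerate(rows, start=1):
        try:
            annotations.append(
                PathogenicityAnnotation(
                    gene=row["gene"].strip(),
                    scope=row["scope"].strip(),
                    pattern=row["pattern"].strip(),
                    verdict=row["verdict"].strip(),
                    source=row["source"].strip(),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return annotations


def read_knowledge_base(path: str | Path) -> list[KnowledgeBaseEntry]:
    rows = _load_rows(
        path, ("gene", "scope", "pattern", "drug", "effect", "tier", "source")
    )
    entries = []
    for i, row in enumerate(rows, start=1):
        try:
            entries.append(
                KnowledgeBaseEntry(
                    gene=row["gene"].strip(),
                    scope=row["scope"].strip(),
                    pattern=row["pattern"].strip(),
                    drug=row["drug"].strip(),
                    effect=row["effect"].strip(),
                    tier=normalize_tier(row["tier"]),
                    source=row["source"].strip(),
                    reference=row.get("reference", "").strip(),
                    cancer_type=row.get("cancer_type", "").strip(),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from None
    return entries


def default_annotations() -> list[PathogenicityAnnotation]:
    with resources.as_file(
        resources.files("ctdna_kinetics.data").joinpath(
            "pathogenicity_annotations.tsv"
        )
    ) as path:
        return read_annotations(path)


def default_knowledge_base() -> list[KnowledgeBaseEntry]:
    with resources.as_file(
        resources.files("ctdna_kinetics.data").joinpath("knowledge_base.tsv")
    ) as path:
        return read_knowledge_base(path)


# --- step 1: pathogenicity filter -------------------------------------------

def _variant_labels(variant) -> tuple[str, str]:
    return (getattr(variant, "hgvs_p", ""), getattr(variant, "hgvs_c", ""))


def _variant_type(variant) -> Optional[MutationType]:
    hgvs_p, hgvs_c = _variant_labels(variant)
    if not hgvs_p and not hgvs_c:
        return None
    from .variants import classify_mutation_type

    return classify_mutation_type(hgvs_p, hgvs_c)


def _pattern_matches_exact(pattern: str, variant) -> bool:
    hgvs_p, hgvs_c = _variant_labels(variant)
    normalized = pattern.replace(" ", "")
    return normalized in (
        hgvs_p.replace(" ", ""), hgvs_c.replace(" ", ""),
    ) and bool(normalized)


def _predicate_satisfied(predicate: str, variant, pathogenic: bool) -> bool:
    predicate = predicate.strip().lower().replace(" ", "_")
    if predicate in ("any_mutation", "mutant", "mutation"):
        return True
    if predicate == "oncogenic_mutation":
        # "oncogenic mutation" entries apply to any variant that survived the
        # pathogenicity filter for this gene.
        return pathogenic
    mutation_type = _variant_type(variant)
    if mutation_type is None:
        return False
    return predicate == mutation_type.value


def filter_pathogenic(
    variants: Sequence, annotations: Sequence[PathogenicityAnnotation]
) -> tuple[list[FilteredVariant], list[FilteredVariant]]:
    """Split variants into (kept, dropped) under the pathogenicity rules.

    Verdict precedence is exact > class > gene; an exact benign verdict
    vetoes everything. Synonymous variants are auto-benign unless an exact
    annotation overrides. The dropped list (verdicts benign/uncertain) feeds
    the report's "unfiltered" appendix. Accepts both VariantCall and
    EmergentVariant inputs (anything with gene/hgvs_p/hgvs_c).
    """
    kept: list[FilteredVariant] = []
    dropped: list[FilteredVariant] = []
    for variant in variants:
        gene_annotations = [a for a in annotations if a.gene == variant.gene]
        exact = [
            a for a in gene_annotations
            if a.scope == "exact_variant" and _pattern_matches_exact(a.pattern, variant)
        ]
        class_level = [
            a for a in gene_annotations
            if a.scope == "variant_class"
            and _predicate_satisfied(a.pattern, variant, pathogenic=True)
        ]
        gene_level = [a for a in gene_annotations if a.scope == "gene_level"]

        exact_benign = [a for a in exact if a.verdict == "benign"]
        if exact_benign:
            dropped.append(
                FilteredVariant(
                    variant=variant, verdict="benign",
                    sources=tuple(a.source for a in exact_benign),
                )
            )
            continue
        exact_pathogenic = [
            a for a in exact if a.verdict in ("pathogenic", "likely_pathogenic")
        ]
        if exact_pathogenic:
            verdict = ("pathogenic" if any(
                a.verdict == "pathogenic" for a in exact_pathogenic
            ) else "likely_pathogenic")
            kept.append(
                FilteredVariant(
                    variant=variant, verdict=verdict,
                    sources=tuple(a.source for a in exact_pathogenic),
                )
            )
            continue
        if _variant_type(variant) is MutationType.SYNONYMOUS:
            dropped.append(
                FilteredVariant(variant=variant, verdict="benign",
                                sources=("auto-benign: synonymous",))
            )
            continue
        for tier_annotations in (class_level, gene_level):
            supporting = [
                a for a in tier_annotations
                if a.verdict in ("pathogenic", "likely_pathogenic")
            ]
            if supporting:
                verdict = ("pathogenic" if any(
                    a.verdict == "pathogenic" for a in supporting
                ) else "likely_pathogenic")
                kept.append(
                    FilteredVariant(
                        variant=variant, verdict=verdict,
                        sources=tuple(a.source for a in supporting),
                    )
                )
                break
        else:
            dropped.append(
                FilteredVariant(variant=variant, verdict="uncertain", sources=())
            )
    return kept, dropped


# --- step 2: knowledge-base matching ----------------------------------------

MATCH_TYPE_BY_SCOPE = {
    "exact_variant": "exact", "variant_class": "class", "gene_level": "gene",
}


def match_therapies(
    filtered: Sequence[FilteredVariant],
    kb: Sequence[KnowledgeBaseEntry],
    weights: MatchWeights = MatchWeights(),
    strict_cancer_type: Optional[str] = None,
) -> list[TherapyMatch]:
    """Match pathogenicity-filtered variants against the knowledge base.

    Per variant and drug: exact matches win; a class-scope entry is used only
    when no exact entry names that drug for this variant, and a gene-level
    entry only when neither does. When an exact and a broader entry agree on
    (drug, effect), only the higher-weight match is emitted; conflicting
    effects for the same drug are BOTH emitted with a conflict flag. Output
    order: descending weight, then drug name, then gene/variant label.
    """
    matches: list[TherapyMatch] = []
    for item in filtered:
        variant = item.variant
        candidates = [e for e in kb if e.gene == variant.gene]
        if strict_cancer_type is not None:
            candidates = [
                e for e in candidates
                if not e.cancer_type
                or e.cancer_type.lower() == strict_cancer_type.lower()
            ]
        per_scope: dict[str, list[KnowledgeBaseEntry]] = {
            "exact_variant": [], "variant_class": [], "gene_level": [],
        }
        for entry in candidates:
            if entry.scope == "exact_variant":
                if _pattern_matches_exact(entry.pattern, variant):
                    per_scope["exact_variant"].append(entry)
            elif entry.scope == "variant_class":
                if _predicate_satisfied(entry.pattern, variant, pathogenic=True):
                    per_scope["variant_class"].append(entry)
            else:
                per_scope["gene_level"].append(entry)
        chosen: dict[tuple[str, str], tuple[KnowledgeBaseEntry, str, float]] = {}
        for scope in SCOPES:  # exact first, then class, then gene
            ranked = sorted(
                per_scope[scope],
                key=lambda e: (-weights.weight(scope, e.tier), e.drug.lower()),
            )
            for entry in ranked:
                key = (entry.drug.lower(), entry.effect)
                if key in chosen:
                    continue  # same (drug, effect) already kept at >= weight
                # a different effect for an already-matched drug is kept too
                # and flagged as a conflict below
                chosen[key] = (
                    entry,
                    MATCH_TYPE_BY_SCOPE[scope],
                    weights.weight(scope, entry.tier),
                )
        drugs_with_conflict = {
            drug for drug, _ in chosen
            if len({effect for d, effect in chosen if d == drug}) > 1
        }
        for (drug, _effect), (entry, match_type, weight) in chosen.items():
            matches.append(
                TherapyMatch(
                    patient_id=getattr(variant, "patient_id", ""),
                    gene=variant.gene,
                    variant_label=(variant.hgvs_p or variant.hgvs_c
                                   or variant.gene),
                    entry=entry,
                    match_type=match_type,
                    weight=weight,
                    conflict=drug in drugs_with_conflict,
                )
            )
    matches.sort(
        key=lambda m: (-m.weight, m.entry.drug.lower(), m.gene, m.variant_label)
    )
    return matches


#: Drug-class entries ("PARP inhibitor", "ATR inhibitors"...) as opposed to
#: named agents; used to distinguish investigational-class suggestions from
#: matches to individually named drugs.
def is_named_agent(drug: str) -> bool:
    return "inhibitor" not in drug.lower()


@dataclass
class PatientActionability:
    patient_id: str
    response: Optional[str]
    emergent: list[EmergentVariant]
    kept: list[FilteredVariant]
    dropped: list[FilteredVariant]
    matches: list[TherapyMatch]

    @property
    def has_match(self) -> bool:
        return bool(self.matches)

    @property
    def has_named_agent_match(self) -> bool:
        return any(is_named_agent(m.entry.drug) for m in self.matches)


def emergent_actionability_report(
    cohort: Cohort,
    kb: Optional[Sequence[KnowledgeBaseEntry]] = None,
    annotations: Optional[Sequence[PathogenicityAnnotation]] = None,
    min_increase: float = 0.0,
    weights: MatchWeights = MatchWeights(),
    **eligibility_options,
) -> list[PatientActionability]:
    """Per-patient report: emergent variants -> filter -> therapy matches.

    Patients are returned in cohort order with their first-evaluation
    response attached, so callers can partition by response (the interesting
    stratum being progressive disease).
    """
    kb = default_knowledge_base() if kb is None else kb
    annotations = default_annotations() if annotations is None else annotations
    report = []
    for patient in cohort:
        emergent = detect_emergent(
            patient, min_increase=min_increase, **eligibility_options
        )
        kept, dropped = filter_pathogenic(emergent, annotations)
        matches = match_therapies(kept, kb, weights=weights)
        report.append(
            PatientActionability(
                patient_id=patient.patient_id,
                response=patient.response,
                emergent=emergent,
                kept=kept,
                dropped=dropped,
                matches=matches,
            )
        )
    return report


def matches_frame(matches: Iterable[TherapyMatch]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": m.patient_id,
                "gene": m.gene,
                "variant": m.variant_label,
                "drug": m.entry.drug,
                "effect": m.entry.effect,
                "tier": m.entry.tier,
                "match_type": m.match_type,
                "weight": m.weight,
                "conflict": m.conflict,
                "source": m.entry.source,
                "reference": m.entry.reference,
            }
            for m in matches
        ],
        columns=["patient_id", "gene", "variant", "drug", "effect", "tier",
                 "match_type", "weight", "conflict", "source", "reference"],
    )
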