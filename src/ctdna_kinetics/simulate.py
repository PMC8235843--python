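"""Synthetic two-timepoint ctDNA cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes: a
24-patient cohort profiled on a targeted panel at baseline and week 4 of
treatment, per-variant VAFs with a heavy-tailed (lognormal) baseline
distribution whose per-patient mean has median near 0.85% and single-digit
maxima, a 0.03% detection limit below which observed VAFs are censored to 0,
occasional heterozygous-germline contaminants near 50% VAF, responder-linked
multiplicative VAF decline at week 4, serum markers with response-decoupled
dynamics (AFP falls in most patients regardless of response; DCP rises in
most), and exponential PFS with a configurable hazard ratio between the
kinetic increase/decrease groups.

Observed absence and a true VAF of 0 are indistinguishable in the emitted
cohort, as in the assay; the :class:`GroundTruth` object preserves the
distinction for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .variants import Cohort, MutationType, PatientRecord, ValidationError, VariantCall

DEFAULT_GENE_PANEL = (
    "TP53", "CTNNB1", "TERT", "ATM", "ARID1A", "PIK3CA", "PTEN", "MTOR",
    "APC", "RB1", "CDKN2A", "NFE2L2", "ESR1", "DDR2", "AR", "RAF1", "MYC",
    "EGFR", "BRAF", "KRAS", "NRAS", "MET", "KIT", "CCND1", "FGFR1", "NOTCH1",
    "SMAD4", "GNAS", "CDK6", "BRCA1", "BRCA2", "JAK2",
)

#: Consequence-type sampling probabilities; promoter variants are emitted on
#: TERT (the panel's promoter signal), splice/frameshift/etc. on any gene.
DEFAULT_TYPE_PROBS = (
    (MutationType.MISSENSE, 0.55),
    (MutationType.NONSENSE, 0.08),
    (MutationType.FRAMESHIFT, 0.08),
    (MutationType.IN_FRAME, 0.04),
    (MutationType.PROMOTER, 0.10),
    (MutationType.SPLICE_SITE, 0.05),
    (MutationType.SYNONYMOUS, 0.10),
)

_AA = "ARNDCQEGHILKMFPSTWYV"
_NT = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort (units as in the reports).

    VAFs are percent; markers are ng/mL (AFP) and mAU/mL (DCP); survival is
    months. ``responder_factor``/``nonresponder_factor`` multiply baseline
    VAFs at week 4 (decline vs growth); ``hazard_ratio`` contrasts the
    kinetic increase group against the decrease group for PFS.
    """

    n_patients: int = 24
    seed: int = 0
    gene_panel: tuple[str, ...] = DEFAULT_GENE_PANEL
    variant_count_mean: float = 6.0  # Poisson lambda
    baseline_vaf_log_mu: float = math.log(0.28)  # log-percent scale
    baseline_vaf_log_sigma: float = 1.9
    responder_fraction: float = 14 / 24
    responder_factor: float = 0.3
    nonresponder_factor: float = 1.5
    week4_noise_log_sd: float = 0.25
    detection_limit_vaf: float = 0.03
    germline_probability: float = 0.05
    germline_band: tuple[float, float] = (45.0, 55.0)
    emergent_probability: float = 0.15  # chance of one week4-only variant
    afp_positive_probability: float = 0.458  # P(baseline AFP >= 20 ng/mL)
    afp_decrease_probability: float = 22 / 24
    dcp_increase_probability: float = 19 / 24
    response_label_noise: float = 0.0
    cr_fraction_of_responders: float = 0.15
    pd_fraction_of_nonresponders: float = 0.4
    pfs_median_decrease_months: float = 9.3
    hazard_ratio: float = 8.4
    os_median_months: float = 17.8
    censoring_median_months: float = 40.0
    type_probs: tuple[tuple[MutationType, float], ...] = DEFAULT_TYPE_PROBS

    def __post_init__(self) -> None:
        for name in ("responder_fraction", "germline_probability",
                     "emergent_probability", "afp_positive_probability",
                     "afp_decrease_probability", "dcp_increase_probability",
                     "response_label_noise"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {value}")
        if self.responder_factor >= self.nonresponder_factor:
            raise ValidationError(
                "responder_factor must be < nonresponder_factor"
            )
        if self.detection_limit_vaf <= 0:
            raise ValidationError("detection_limit_vaf must be > 0")
        if self.variant_count_mean <= 0:
            raise ValidationError(
                "variant_count_mean must be > 0 (an all-empty cohort cannot "
                "exercise responder-factor kinetics)"
            )


@dataclass
class PatientTruth:
    patient_id: str
    responder: bool
    true_vaf_baseline: dict[tuple, float] = field(default_factory=dict)
    true_vaf_week4: dict[tuple, float] = field(default_factory=dict)
    germline_keys: set[tuple] = field(default_factory=set)
    group_hazard: float = float("nan")


@dataclass
class GroundTruth:
    config: SimulationConfig
    patients: dict[str, PatientTruth] = field(default_factory=dict)


def _sample_type(rng: np.random.Generator, probs) -> MutationType:
    types, weights = zip(*probs)
    weights = np.asarray(weights, dtype=float)
    return rng.choice(np.array(types, dtype=object), p=weights / weights.sum())


def _hgvs_for_type(
    rng: np.random.Generator, mutation_type: MutationType
) -> tuple[str, str]:
    """Template HGVS strings that round-trip through the classifier."""
    pos = int(rng.integers(20, 2999))
    ref, alt = rng.choice(list(_AA)), rng.choice(list(_AA))
    nt_ref, nt_alt = rng.choice(list(_NT)), rng.choice(list(_NT))
    while nt_alt == nt_ref:
        nt_alt = rng.choice(list(_NT))
    if mutation_type is MutationType.MISSENSE:
        while alt == ref:
            alt = rng.choice(list(_AA))
        return f"{ref}{pos}{alt}", f"c.{pos * 3}{nt_ref}>{nt_alt}"
    if mutation_type is MutationType.NONSENSE:
        return f"{ref}{pos}*", f"c.{pos * 3}{nt_ref}>{nt_alt}"
    if mutation_type is MutationType.FRAMESHIFT:
        return f"{ref}{pos}fs", f"{nt_ref}>{nt_ref}{nt_alt}"
    if mutation_type is MutationType.IN_FRAME:
        return f"{ref}{pos}del", ""
    if mutation_type is MutationType.PROMOTER:
        return "", f"c.-{int(rng.integers(20, 200))}{nt_ref}>{nt_alt}"
    if mutation_type is MutationType.SPLICE_SITE:
        offset = rng.choice(["-1", "+1", "-2", "+2"])
        return "", f"c.{pos}{offset}{nt_ref}>{nt_alt}"
    if mutation_type is MutationType.SYNONYMOUS:
        return f"{ref}{pos}{ref}", f"c.{pos * 3}{nt_ref}>{nt_alt}"
    return "", ""


def _observe(vaf: float, limit: float) -> float:
    """Detection-limit censoring: sub-limit signal reads as absence."""
    if vaf < limit:
        return 0.0
    return min(float(vaf), 100.0)


def simulate_cohort(config: SimulationConfig) -> tuple[Cohort, GroundTruth]:
    """Draw one cohort plus its generating ground truth.

    Deterministic in ``config.seed``: identical configs give byte-identical
    cohorts. Patients whose observed panels are empty at both timepoints are
    emitted anyway (they exercise the exclusion path, as a no-ctDNA patient
    would).
    """
    rng = np.random.default_rng(config.seed)
    truth = GroundTruth(config=config)
    patients: list[PatientRecord] = []
    lam_decrease = math.log(2) / config.pfs_median_decrease_months
    lam_censor = math.log(2) / config.censoring_median_months
    lam_os = math.log(2) / config.os_median_months
    for index in range(config.n_patients):
        patient_id = f"SIM-{index + 1:03d}"
        responder = bool(rng.random() < config.responder_fraction)
        patient_truth = PatientTruth(patient_id=patient_id, responder=responder)
        n_variants = int(rng.poisson(config.variant_count_mean))
        genes = rng.choice(
            np.array(config.gene_panel, dtype=object),
            size=min(n_variants, len(config.gene_panel)),
            replace=False,
        )
        factor = (config.responder_factor if responder
                  else config.nonresponder_factor)
        baseline_calls: list[VariantCall] = []
        week4_calls: list[VariantCall] = []
        for gene in genes:
            mutation_type = _sample_type(rng, config.type_probs)
            if mutation_type is MutationType.PROMOTER:
                gene = "TERT"
                if any(c.gene == "TERT" for c in baseline_calls):
                    continue
            hgvs_p, hgvs_c = _hgvs_for_type(rng, mutation_type)
            variant_class = (
                "indel"
                if mutation_type in (MutationType.FRAMESHIFT, MutationType.IN_FRAME)
                else "SNV"
            )
            true_baseline = float(np.exp(rng.normal(
                config.baseline_vaf_log_mu, config.baseline_vaf_log_sigma
            )))
            true_baseline = min(true_baseline, 100.0)
            noise = float(np.exp(rng.normal(0.0, config.week4_noise_log_sd)))
            true_week4 = min(true_baseline * factor * noise, 100.0)
            key = (str(gene), variant_class, hgvs_p, hgvs_c)
            patient_truth.true_vaf_baseline[key] = true_baseline
            patient_truth.true_vaf_week4[key] = true_week4
            for timepoint, true_vaf, bucket in (
                ("baseline", true_baseline, baseline_calls),
                ("week4", true_week4, week4_calls),
            ):
                observed = _observe(true_vaf, config.detection_limit_vaf)
                if observed == 0.0:
                    continue  # unreported: absence and 0 are indistinguishable
                bucket.append(
                    VariantCall(
                        patient_id=patient_id, timepoint=timepoint,
                        gene=str(gene), variant_class=variant_class,
                        hgvs_p=hgvs_p, hgvs_c=hgvs_c, vaf=observed,
                    )
                )
        if rng.random() < config.emergent_probability:
            mutation_type = MutationType.MISSENSE
            hgvs_p, hgvs_c = _hgvs_for_type(rng, mutation_type)
            gene = str(rng.choice(np.array(config.gene_panel, dtype=object)))
            vaf = float(np.exp(rng.normal(
                config.baseline_vaf_log_mu, config.baseline_vaf_log_sigma
            )))
            vaf = _observe(vaf, config.detection_limit_vaf)
            if vaf > 0:
                key = (gene, "SNV", hgvs_p, hgvs_c)
                patient_truth.true_vaf_baseline[key] = 0.0
                patient_truth.true_vaf_week4[key] = vaf
                week4_calls.append(
                    VariantCall(
                        patient_id=patient_id, timepoint="week4", gene=gene,
                        variant_class="SNV", hgvs_p=hgvs_p, hgvs_c=hgvs_c,
                        vaf=vaf,
                    )
                )
        if rng.random() < config.germline_probability:
            lo, hi = config.germline_band
            vaf = float(rng.uniform(lo, hi))
            hgvs_p, hgvs_c = _hgvs_for_type(rng, MutationType.MISSENSE)
            gene = str(rng.choice(np.array(config.gene_panel, dtype=object)))
            key = (gene, "SNV", hgvs_p, hgvs_c)
            patient_truth.germline_keys.add(key)
            for timepoint, bucket in (
                ("baseline", baseline_calls), ("week4", week4_calls),
            ):
                # germline allele balance barely moves between draws
                observed = min(max(vaf + float(rng.normal(0.0, 0.5)), 0.0), 100.0)
                bucket.append(
                    VariantCall(
                        patient_id=patient_id, timepoint=timepoint, gene=gene,
                        variant_class="SNV", hgvs_p=hgvs_p, hgvs_c=hgvs_c,
                        vaf=observed,
                    )
                )

        # --- response label ---------------------------------------------
        if responder:
            response = "CR" if rng.random() < config.cr_fraction_of_responders else "PR"
        else:
            response = "PD" if rng.random() < config.pd_fraction_of_nonresponders else "SD"
        if rng.random() < config.response_label_noise:
            response = str(rng.choice(np.array(["PD", "SD", "PR", "CR"], dtype=object)))

        # --- serum markers ------------------------------------------------
        afp_positive = rng.random() < config.afp_positive_probability
        afp_baseline = (
            float(np.exp(rng.normal(math.log(150.0), 1.2))) + 20.0
            if afp_positive else float(rng.uniform(0.5, 19.0))
        )
        if rng.random() < config.afp_decrease_probability:
            afp_week4 = afp_baseline * float(rng.uniform(0.4, 0.95))
        else:
            afp_week4 = afp_baseline * float(rng.uniform(1.05, 1.8))
        dcp_baseline = float(np.exp(rng.normal(math.log(180.0), 1.5))) + 13.0
        if rng.random() < config.dcp_increase_probability:
            dcp_week4 = dcp_baseline * float(rng.uniform(1.05, 2.5))
        else:
            dcp_week4 = dcp_baseline * float(rng.uniform(0.4, 0.95))

        # --- survival, conditioned on the observed direction group --------
        from .kinetics import compute_change_and_direction

        shell = PatientRecord(
            patient_id=patient_id,
            baseline_calls=baseline_calls,
            week4_calls=week4_calls,
        )
        direction = compute_change_and_direction(
            shell, germline_band=config.germline_band
        ).direction
        hazard = lam_decrease * (
            config.hazard_ratio if direction == "increase" else 1.0
        )
        patient_truth.group_hazard = hazard
        pfs_raw = float(rng.exponential(1.0 / hazard))
        censor = float(rng.exponential(1.0 / lam_censor))
        pfs_months = max(min(pfs_raw, censor), 1e-3)
        pfs_event = pfs_raw <= censor
        os_raw = float(rng.exponential(1.0 / lam_os))
        os_censor = float(rng.exponential(1.0 / lam_censor))
        os_months = max(min(os_raw, os_censor), 1e-3)
        os_event = os_raw <= os_censor

        tumor_baseline = float(rng.uniform(10.0, 120.0))
        tumor_factor = factor ** 0.5  # size responds more slowly than VAF
        tumor_week4 = tumor_baseline * tumor_factor * float(
            np.exp(rng.normal(0.0, 0.1))
        )
        patients.append(
            PatientRecord(
                patient_id=patient_id,
                baseline_calls=baseline_calls,
                week4_calls=week4_calls,
                afp_baseline=round(afp_baseline, 1),
                afp_week4=round(afp_week4, 1),
                dcp_baseline=round(dcp_baseline, 1),
                dcp_week4=round(dcp_week4, 1),
                tumor_size_baseline=round(tumor_baseline, 1),
                tumor_size_week4=round(tumor_week4, 1),
                response=response,
                pfs_months=round(pfs_months, 3),
                pfs_event=bool(pfs_event),
                os_months=round(os_months, 3),
                os_event=bool(os_event),
            )
        )
        truth.patients[patient_id] = patient_truth
    cohort = Cohort(
        patients=patients, detection_limit_vaf=config.detection_limit_vaf
    )
    return cohort, truth


def classifier_recovery(
    cohort: Cohort, truth: GroundTruth, **kinetics_options
) -> dict[str, float]:
    """Sensitivity/specificity of the kinetic direction call against the true
    responder status (decrease predicts responder); excluded patients are
    not scored."""
    from .kinetics import summarize_cohort

    kinetics_options.setdefault("germline_band", truth.config.germline_band)
    tp = fp = tn = fn = 0
    for summary in summarize_cohort(cohort, **kinetics_options):
        if summary.direction == "excluded":
            continue
        responder = truth.patients[summary.patient_id].responder
        predicted = summary.direction == "decrease"
        if responder and predicted:
            tp += 1
        elif responder:
            fn += 1
        elif predicted:
            fp += 1
        else:
            tn += 1
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "n_classified": tp + fp + tn + fn,
    }


# --- deterministic worked-example and report fixture -------------------------

def worked_example_patient() -> PatientRecord:
    """The four-gene illustration of the VAF_mean definition.

    Baseline: A=11%, B=4%, C=0%, D=0%; week 4: A=12%, B=4%, C=2%, D=0%.
    Gene D, undetected at both timepoints, is excluded; the means are 5 and 6
    and the change is +1.
    """
    def call(timepoint, gene, vaf):
        return VariantCall(
            patient_id="EX-01", timepoint=timepoint, gene=gene,
            variant_class="SNV", hgvs_p="M1V", vaf=vaf,
        )

    return PatientRecord(
        patient_id="EX-01",
        baseline_calls=[
            call("baseline", "GENEA", 11.0),
            call("baseline", "GENEB", 4.0),
            call("baseline", "GENEC", 0.0),
            call("baseline", "GENED", 0.0),
        ],
        week4_calls=[
            call("week4", "GENEA", 12.0),
            call("week4", "GENEB", 4.0),
            call("week4", "GENEC", 2.0),
            call("week4", "GENED", 0.0),
        ],
    )


def _fx(patient_id, timepoint, gene, variant_class, hgvs_p, hgvs_c, vaf):
    return VariantCall(
        patient_id=patient_id, timepoint=timepoint, gene=gene,
        variant_class=variant_class, hgvs_p=hgvs_p, hgvs_c=hgvs_c, vaf=vaf,
    )


#: (patient, gene, class, hgvs_p, hgvs_c, vaf_baseline, vaf_week4) for the
#: emergent variants of the four progressive-disease patients in the
#: published report; vaf_baseline 0 encodes "novelly detected".
_EMERGENT_ROWS = (
    ("HG-12", "ARID1A", "indel", "A2027fs", "C>CA", 0.30, 0.80),
    ("HG-06", "CTNNB1", "SNV", "G34V", "G>T", 0.40, 0.90),
    ("HG-12", "CTNNB1", "SNV", "S33C", "C>G", 0.50, 1.10),
    ("HG-06", "DDR2", "SNV", "W778L", "G>T", 0.0, 0.60),
    ("HG-18", "ESR1", "SNV", "R477*", "C>T", 0.0, 0.30),
    ("HG-06", "TP53", "SNV", "G245S", "C>T", 0.60, 1.20),
    ("HG-18", "TP53", "SNV", "C238S", "A>T", 0.0, 0.40),
    ("HG-22", "AR", "SNV", "R609K", "G>A", 0.0, 0.08),
    ("HG-22", "ATM", "SNV", "R2832H", "G>A", 0.10, 0.19),
    ("HG-22", "ATM", "SNV", "G2891D", "G>A", 0.0, 0.15),
    ("HG-22", "ATM", "indel", "S1905fs", "T>TA", 0.05, 0.12),
    ("HG-12", "NFE2L2", "SNV", "D29G", "T>C", 0.0, 0.25),
    ("HG-06", "TERT", "SNV", "", "c.-124C>G", 0.35, 0.70),
    ("HG-06", "TERT", "SNV", "", "c.-146G>A", 0.20, 0.45),
)


def make_paper_fixture() -> Cohort:
    """A deterministic 24-patient cohort shaped like the published study.

    The direction-by-response margins reproduce all five diagnostic blocks
    (VAF_mean-change; AFP all cases and baseline >= 20 ng/mL; DCP all cases
    and baseline >= 40 mAU/mL) simultaneously, one patient carries no ctDNA
    at either timepoint (the exclusion analogue), and the four
    progressive-disease patients carry the published emergent-variant rows.
    Every number here is synthetic apart from those published margins and
    variant identities.
    """
    pd_ids = ("HG-06", "HG-12", "HG-18", "HG-22")
    sd_ids = ("HG-02", "HG-05", "HG-19", "HG-21", "HG-23", "HG-24")
    prcr_ids = ("HG-01", "HG-03", "HG-04", "HG-07", "HG-08", "HG-09",
                "HG-10", "HG-11", "HG-13", "HG-14", "HG-15", "HG-16",
                "HG-17", "HG-20")
    # VAF direction: PD + {HG-23, HG-24} increase; HG-21 excluded; rest decrease
    vaf_increase_sd = {"HG-23", "HG-24"}
    # AFP: increase only in HG-06 (PD) and HG-03 (PR/CR); both AFP < 20
    afp_increase = {"HG-06", "HG-03"}
    afp_ge20 = {"HG-18", "HG-22",              # PD, both decrease
                "HG-02",                        # SD
                "HG-01", "HG-04", "HG-07", "HG-08", "HG-09", "HG-10",
                "HG-11", "HG-13"}               # PR/CR (8)
    # DCP: decrease only in HG-19 (SD) and HG-01/04/07/08 (PR/CR)
    dcp_decrease = {"HG-19", "HG-01", "HG-04", "HG-07", "HG-08"}
    dcp_ge40 = {"HG-06", "HG-12", "HG-18", "HG-22",            # PD
                "HG-02", "HG-05", "HG-21", "HG-24", "HG-19",   # SD (5)
                "HG-09", "HG-10", "HG-11", "HG-13", "HG-14", "HG-15",  # PR/CR inc
                "HG-01", "HG-04", "HG-07"}                     # PR/CR dec (3)

    def response_of(patient_id: str) -> str:
        if patient_id in pd_ids:
            return "PD"
        if patient_id in sd_ids:
            return "SD"
        # two complete responses for flavor, the rest partial
        return "CR" if patient_id in ("HG-09", "HG-14") else "PR"

    #: flavor variants echoing the per-type opposite-direction singletons
    flavor = {
        "HG-01": ("TP53", "SNV", "", "c.97-1G>A"),      # splice site
        "HG-05": ("RB1", "SNV", "R552*", ""),           # nonsense
        "HG-09": ("TP53", "SNV", "L130F", ""),          # missense
        "HG-19": ("TP53", "SNV", "", "c.993+1G>T"),     # splice site
    }
    patients = []
    all_ids = sorted(pd_ids + sd_ids + prcr_ids,
                     key=lambda s: int(s.split("-")[1]))
    for patient_id in all_ids:
        baseline: list[VariantCall] = []
        week4: list[VariantCall] = []
        if patient_id == "HG-21":
            pass  # no ctDNA at either timepoint
        elif patient_id in pd_ids:
            for row in _EMERGENT_ROWS:
                if row[0] != patient_id:
                    continue
                _, gene, klass, hgvs_p, hgvs_c, vaf_b, vaf_w4 = row
                if vaf_b > 0:
                    baseline.append(
                        _fx(patient_id, "baseline", gene, klass, hgvs_p,
                            hgvs_c, vaf_b)
                    )
                week4.append(
                    _fx(patient_id, "week4", gene, klass, hgvs_p, hgvs_c,
                        vaf_w4)
                )
            if patient_id == "HG-12":
                # known promoter hotspot present at both timepoints
                baseline.append(
                    _fx(patient_id, "baseline", "TERT", "SNV", "",
                        "c.-124C>T", 0.90)
                )
                week4.append(
                    _fx(patient_id, "week4", "TERT", "SNV", "",
                        "c.-124C>T", 0.60)
                )
        else:
            increase = patient_id in vaf_increase_sd
            if patient_id in flavor:
                # a singleton moving AGAINST the overall (decreasing)
                # direction, echoing the published per-type discordances,
                # plus a dominant frameshift carrying the overall decline
                gene, klass, hgvs_p, hgvs_c = flavor[patient_id]
                baseline.append(
                    _fx(patient_id, "baseline", gene, klass, hgvs_p, hgvs_c, 1.0)
                )
                week4.append(
                    _fx(patient_id, "week4", gene, klass, hgvs_p, hgvs_c, 1.3)
                )
                baseline.append(
                    _fx(patient_id, "baseline", "ARID1A", "indel",
                        "E1000fs", "", 2.8)
                )
                week4.append(
                    _fx(patient_id, "week4", "ARID1A", "indel",
                        "E1000fs", "", 1.0)
                )
            else:
                vaf_b, vaf_w4 = (1.0, 2.0) if increase else (2.0, 1.0)
                baseline.append(
                    _fx(patient_id, "baseline", "TP53", "SNV", "R175H", "", vaf_b)
                )
                week4.append(
                    _fx(patient_id, "week4", "TP53", "SNV", "R175H", "", vaf_w4)
                )
        if patient_id == "HG-04":
            # heterozygous germline contaminant, flagged out by the 40-60 band
            baseline.append(
                _fx(patient_id, "baseline", "APC", "SNV", "I1307K", "", 50.2)
            )
            week4.append(
                _fx(patient_id, "week4", "APC", "SNV", "I1307K", "", 50.4)
            )
        afp_baseline = {
            "HG-18": 221.0, "HG-22": 3834.0,
        }.get(patient_id, 50.0 if patient_id in afp_ge20 else 5.0)
        if patient_id in afp_increase:
            afp_week4 = round(afp_baseline * 1.5, 1)
        else:
            afp_week4 = {"HG-18": 168.0, "HG-22": 1273.0}.get(
                patient_id, round(afp_baseline * 0.76, 1)
            )
        dcp_baseline = 180.0 if patient_id in dcp_ge40 else 25.0
        dcp_week4 = round(
            dcp_baseline * (0.7 if patient_id in dcp_decrease else 1.4), 1
        )
        response = response_of(patient_id)
        index = int(patient_id.split("-")[1])
        if response == "PD":
            pfs, event = 1.2 + 0.2 * index, True
        elif patient_id in vaf_increase_sd:
            pfs, event = 6.1 if patient_id == "HG-23" else 3.4, True
        elif response == "SD":
            pfs, event = 4.0 + 0.3 * index, True
        else:
            pfs, event = 8.0 + 0.4 * index, index % 3 != 0
        patients.append(
            PatientRecord(
                patient_id=patient_id,
                baseline_calls=baseline,
                week4_calls=week4,
                afp_baseline=afp_baseline,
                afp_week4=afp_week4,
                dcp_baseline=dcp_baseline,
                dcp_week4=dcp_week4,
                tumor_size_baseline=30.0 + index,
                tumor_size_week4=round((30.0 + index) * (1.3 if response == "PD" else 0.8), 1),
                response=response,
                pfs_months=round(pfs, 2),
                pfs_event=event,
                os_months=round(pfs + 8.0, 2),
                os_event=index % 2 == 0,
            )
        )
    return Cohort(patients=patients, detection_limit_vaf=0.03)
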