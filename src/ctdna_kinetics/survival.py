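"""Kaplan-Meier curves, log-rank comparison, proportional-hazards fitting
and bootstrap optimism correction of the concordance index.

The product-limit estimator and the log-rank test are computed with
``lifelines``; the Cox model uses ``statsmodels`` PHReg with Breslow tie
handling and Wald confidence intervals. The bootstrap optimism correction is
Harrell-style: refit on each resample, measure the apparent-minus-original
concordance gap, and subtract the mean gap from the full-data concordance.
Somers' D is reported alongside (D = 2C - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from statsmodels.duration.hazard_regression import PHReg

from .variants import Cohort, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float
    event: bool
    groups: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValidationError(
                f"patient {self.patient_id}: time must be > 0, got {self.time}"
            )


@dataclass
class KMCurve:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_time: Optional[float]


@dataclass
class LogRankResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float


@dataclass
class CovariateEstimate:
    name: str
    coefficient: float
    se: float
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class PHFitResult:
    covariates: list[CovariateEstimate]
    concordance: float
    converged: bool
    n: int
    n_events: int
    warnings: list[str] = field(default_factory=list)


@dataclass
class OptimismResult:
    apparent_concordance: float
    optimism: float
    corrected_concordance: float
    corrected_somers_d: float
    b_requested: int
    b_used: int
    n_skipped: int
    seed: int
    warnings: list[str] = field(default_factory=list)


def cohort_survival_records(
    cohort: Cohort, endpoint: str = "pfs"
) -> list[SurvivalRecord]:
    """Extract one endpoint's records; patients missing the endpoint are
    dropped."""
    if endpoint not in ("pfs", "os"):
        raise ValidationError(f"unknown endpoint {endpoint!r}")
    records = []
    for patient in cohort:
        time = getattr(patient, f"{endpoint}_months")
        event = getattr(patient, f"{endpoint}_event")
        if time is None or event is None:
            continue
        records.append(
            SurvivalRecord(patient_id=patient.patient_id, time=time, event=event)
        )
    return records


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate with right censoring.

    Ties at a time are processed events-before-censoring. The median is the
    earliest time where survival drops to <= 0.5; ``None`` when the curve
    never reaches it.
    """
    if not records:
        raise ValidationError("km_estimate requires >= 1 record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)
    fitter = KaplanMeierFitter()
    fitter.fit(times, event_observed=events)
    event_table = fitter.event_table
    observed_times = event_table.index.to_numpy(dtype=float)
    mask = observed_times > 0  # drop the t=0 anchor row
    observed_times = observed_times[mask]
    survival = fitter.survival_function_["KM_estimate"].to_numpy()[mask]
    at_risk = event_table["at_risk"].to_numpy()[mask]
    # earliest time where the curve reaches one half (inclusive)
    reached = np.nonzero(survival <= 0.5 + 1e-12)[0]
    median = float(observed_times[reached[0]]) if reached.size else None
    return KMCurve(
        event_times=observed_times,
        survival=survival,
        at_risk=at_risk,
        median_time=median,
    )


def logrank_test(
    records: Sequence[SurvivalRecord], group_key: str = "group"
) -> LogRankResult:
    """K-sample log-rank test over the labels in ``record.groups[group_key]``.

    Observed-minus-expected statistic with hypergeometric variance; the
    p-value is the chi-square upper tail on k-1 degrees of freedom.
    """
    labels = [r.groups.get(group_key) for r in records]
    if any(label is None for label in labels):
        raise ValidationError(f"every record needs a {group_key!r} label")
    unique = sorted(set(labels))
    if len(unique) < 2:
        raise ValidationError("log-rank needs >= 2 non-empty groups")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    result = multivariate_logrank_test(times, labels, events)
    return LogRankResult(
        chi_square=float(result.test_statistic),
        degrees_of_freedom=len(unique) - 1,
        p_value=float(result.p_value),
    )


def _design(
    frame: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for covariate in covariates:
        if frame[covariate].nunique() <= 1:
            raise ValidationError(
                f"covariate {covariate!r} is constant; no hazard contrast exists"
            )
    X = frame[list(covariates)].to_numpy(dtype=float)
    time = frame["time"].to_numpy(dtype=float)
    status = frame["event"].to_numpy(dtype=int)
    return X, time, status


def ph_fit(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    alpha: float = 0.05,
) -> PHFitResult:
    """Cox proportional-hazards fit (Breslow ties, Wald CIs).

    ``frame`` needs columns ``time``, ``event`` and the covariates.
    Monotone-likelihood/separation problems surface as a flagged
    non-converged result (enormous standard errors), never a crash.
    """
    if frame["event"].sum() < 2:
        raise ValidationError("ph_fit requires >= 2 observed events")
    X, time, status = _design(frame, covariates)
    fit_warnings: list[str] = []
    converged = True
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            model = PHReg(time, X, status=status, ties="breslow")
            result = model.fit(disp=False)
        for w in caught:
            fit_warnings.append(str(w.message))
    except Exception as exc:  # noqa: BLE001 - flagged, not fatal
        return PHFitResult(
            covariates=[],
            concordance=float("nan"),
            converged=False,
            n=len(frame),
            n_events=int(status.sum()),
            warnings=[f"fit failed: {exc}"],
        )
    params = np.asarray(result.params, dtype=float)
    bse = np.asarray(result.bse, dtype=float)
    if not np.all(np.isfinite(params)):
        return PHFitResult(
            covariates=[],
            concordance=float("nan"),
            converged=False,
            n=len(frame),
            n_events=int(status.sum()),
            warnings=fit_warnings + ["non-finite coefficients"],
        )
    if not np.all(np.isfinite(bse)) or np.any(bse > 1e3):
        converged = False
        fit_warnings.append("possible separation / monotone likelihood")
    from scipy import stats

    z = stats.norm.ppf(1 - alpha / 2)
    estimates = []
    with np.errstate(over="ignore"):
        for name, beta, se in zip(covariates, params, bse):
            p_value = 2 * stats.norm.sf(abs(beta) / se) if se > 0 else float("nan")
            estimates.append(
                CovariateEstimate(
                    name=name,
                    coefficient=float(beta),
                    se=float(se),
                    hazard_ratio=float(np.exp(beta)),
                    ci_low=float(np.exp(beta - z * se)),
                    ci_high=float(np.exp(beta + z * se)),
                    p_value=float(p_value),
                )
            )
    linear_predictor = X @ params
    try:
        c_index = concordance_index(time, -linear_predictor, status)
    except ZeroDivisionError:  # no admissible pairs (e.g. single event time)
        c_index = float("nan")
        converged = False
        fit_warnings.append("concordance undefined: no admissible pairs")
    return PHFitResult(
        covariates=estimates,
        concordance=float(c_index),
        converged=converged,
        n=len(frame),
        n_events=int(status.sum()),
        warnings=fit_warnings,
    )


def export_design_matrix(
    frame: pd.DataFrame, covariates: Sequence[str], path
) -> None:
    """Hook for external penalized (e.g. lasso) fitting: write the design
    matrix with time/event columns as TSV."""
    frame[["time", "event", *covariates]].to_csv(path, sep="\t", index=False)


def bootstrap_optimism(
    frame: pd.DataFrame,
    covariates: Sequence[str],
    B: int = 1000,
    seed: int = 0,
) -> OptimismResult:
    """Harrell bootstrap optimism correction of the concordance index.

    For each of B resamples (drawn with replacement): fit the model on the
    resample, record (concordance on the resample) - (concordance of that
    fit applied to the original data). The mean gap is the optimism;
    corrected C = apparent C - optimism. Non-convergent resample fits are
    skipped and counted; > 20% skipped adds a warning to the result.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    apparent_fit = ph_fit(frame, covariates)
    if not apparent_fit.converged:
        raise ValidationError("full-data fit did not converge")
    apparent = apparent_fit.concordance
    rng = np.random.default_rng(seed)
    time = frame["time"].to_numpy(dtype=float)
    status = frame["event"].to_numpy(dtype=int)
    X = frame[list(covariates)].to_numpy(dtype=float)
    n = len(frame)
    optimisms = []
    skipped = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        boot = frame.iloc[idx].reset_index(drop=True)
        try:
            boot_fit = ph_fit(boot, covariates)
        except ValidationError:
            skipped += 1
            continue
        if (not boot_fit.converged or not boot_fit.covariates
                or not np.isfinite(boot_fit.concordance)):
            skipped += 1
            continue
        params = np.array([c.coefficient for c in boot_fit.covariates])
        lp_original = X @ params
        c_original = concordance_index(time, -lp_original, status)
        optimisms.append(boot_fit.concordance - c_original)
    result_warnings = []
    if skipped > 0.2 * B:
        result_warnings.append(
            f"{skipped}/{B} bootstrap fits skipped (non-convergence)"
        )
        logger.warning(result_warnings[-1])
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    corrected = apparent - optimism
    return OptimismResult(
        apparent_concordance=apparent,
        optimism=optimism,
        corrected_concordance=corrected,
        corrected_somers_d=2 * corrected - 1,
        b_requested=B,
        b_used=len(optimisms),
        n_skipped=skipped,
        seed=seed,
        warnings=result_warnings,
    )


def median_split(values: Sequence[float]) -> list[str]:
    """Dichotomize a continuous covariate at its median.

    Values equal to the median land in the "high" group, matching the
    convention of reporting the high group as ">= median".
    """
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    return ["high" if v >= med else "low" for v in arr]
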