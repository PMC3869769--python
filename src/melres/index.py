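"""Resistance-index assignment and clinical evaluation.

This stage turns a discovery-stage signature into a clinically weighted
resistance index (RI):

1. *Reweighting* — a single multivariate Cox regression of the training
   cohort's progression-free survival on the signature probes' expression;
   the fitted coefficients become the signature's new weights.
2. *Scoring* — each patient's RI is the linear predictor
   ``sum(new_weight * expression)``; no centring or rescaling, so weights
   transfer directly between cohorts measured on the same log scale.
3. *Stratification* — cohort-internal percentiles cut at 25 and 75 define
   sensitive / intermediate / resistant strata; the sensitive and
   intermediate strata merge into a single non-resistant group for the
   dichotomised Cox analyses.
4. *Evaluation* — Kaplan-Meier curves and log-rank tests across strata,
   univariate and covariate-adjusted Cox models of the merged dichotomy,
   restricted-cubic-spline log relative-hazard curves in the RI, and
   time-dependent ROC at configurable horizons, for both PFS and OS.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import (
    DegenerateStratificationError,
    MissingProbeError,
    UnweightedSignatureError,
)
from .signature import GeneSignature
from .simulate import PatientCohort
from .survival import (
    CoxPH,
    KMCurve,
    LogRankResult,
    RCSCurve,
    SurvivalData,
    TdROC,
    km_estimate,
    logrank_test,
    rcs_loghazard,
    td_roc,
)

__all__ = [
    "reweight_signature",
    "compute_ri",
    "stratify",
    "RiskAssignment",
    "ResistanceIndexModel",
    "EndpointEvaluation",
    "CohortEvaluation",
    "evaluate_cohort",
    "hazard_ratio_report",
]

STRATA = ("sensitive", "intermediate", "resistant")
MERGED = ("non_resistant", "resistant")


def _signature_matrix(signature: GeneSignature, expression: pd.DataFrame) -> pd.DataFrame:
    """Patients-by-probes design matrix for the signature, validating presence."""
    missing = [p for p in signature.probe_ids if p not in expression.index]
    if missing:
        raise MissingProbeError(missing)
    return expression.loc[signature.probe_ids].T


def reweight_signature(
    signature: GeneSignature,
    training: PatientCohort,
    endpoint: str = "pfs",
    standardize: bool = False,
    ties: str = "efron",
) -> GeneSignature:
    """Reweight a signature by multivariate Cox regression on a training cohort.

    Each retained probe's ``new_weight`` is its coefficient in a single
    Cox fit of the chosen endpoint on the signature probes' expression.
    Probes with zero expression variance are dropped with a warning and
    recorded on the returned signature's ``dropped_probes``.
    """
    X = _signature_matrix(signature, training.expression)
    variances = X.to_numpy().std(axis=0)
    dropped = [c for c, v in zip(X.columns, variances) if v == 0]
    if dropped:
        warnings.warn(
            f"dropping zero-variance probe(s) from signature: {', '.join(dropped)}",
            UserWarning,
        )
        X = X.drop(columns=dropped)
    if standardize:
        X = (X - X.mean()) / X.std(ddof=1)
    time, event = training.endpoint(endpoint)
    fit = CoxPH(ties=ties).fit(X, SurvivalData(time, event))
    new_weights = dict(zip(X.columns, fit.coef_))
    result = signature.with_new_weights(new_weights, dropped_probes=dropped)
    return result


def compute_ri(signature: GeneSignature, expression: pd.DataFrame) -> pd.Series:
    """Per-sample resistance index: the signature-weighted expression sum.

    ``ri = sum_probes new_weight * expression``, with no centring or
    rescaling, so the index is exactly the Cox linear predictor under the
    training-derived weights.
    """
    if not signature.has_new_weights:
        raise UnweightedSignatureError(
            "signature has no (finite) new weights; reweight it on a training "
            "cohort before scoring"
        )
    X = _signature_matrix(signature, expression)
    w = signature.new_weights.loc[list(X.columns)]
    ri = X.to_numpy() @ w.to_numpy()
    return pd.Series(ri, index=X.index, name="ri")


@dataclasses.dataclass
class RiskAssignment:
    """Per-patient RI, cohort percentile and stratum labels."""

    frame: pd.DataFrame  # columns: ri, percentile, stratum, merged_stratum

    @property
    def ri(self) -> pd.Series:
        return self.frame["ri"]

    @property
    def percentile(self) -> pd.Series:
        return self.frame["percentile"]

    @property
    def stratum(self) -> pd.Series:
        return self.frame["stratum"]

    @property
    def merged_stratum(self) -> pd.Series:
        return self.frame["merged_stratum"]

    @property
    def resistant_indicator(self) -> np.ndarray:
        return (self.frame["merged_stratum"] == "resistant").to_numpy().astype(float)

    def counts(self) -> pd.Series:
        return self.frame["stratum"].value_counts().reindex(STRATA, fill_value=0)


def stratify(ri: pd.Series) -> RiskAssignment:
    """Cut cohort-internal RI percentiles at 25 and 75.

    Percentiles are averaged ranks scaled to [0, 100]; boundary samples
    assign downward (percentile <= 25 is sensitive, <= 75 intermediate,
    above 75 resistant).  The merged dichotomy pools sensitive and
    intermediate into ``non_resistant``.
    """
    ri = pd.Series(ri)
    n = len(ri)
    if n < 4:
        raise ValueError("stratification requires at least 4 samples")
    if ri.nunique() == 1:
        raise DegenerateStratificationError("all resistance indices are identical")
    pct = ri.rank(method="average") / n * 100.0
    stratum = pd.Series(
        np.where(pct <= 25.0, "sensitive",
                 np.where(pct <= 75.0, "intermediate", "resistant")),
        index=ri.index, name="stratum",
    )
    merged = stratum.map(
        lambda s: "resistant" if s == "resistant" else "non_resistant"
    ).rename("merged_stratum")
    frame = pd.DataFrame(
        {"ri": ri, "percentile": pct, "stratum": stratum, "merged_stratum": merged}
    )
    return RiskAssignment(frame)


class ResistanceIndexModel(BaseEstimator):
    """Signature reweighting and RI scoring as a fit/predict estimator.

    ``fit`` performs the Cox reweighting on a training cohort; ``predict``
    scores any expression matrix sharing the probe space.
    """

    def __init__(self, signature: GeneSignature, endpoint: str = "pfs",
                 standardize: bool = False, ties: str = "efron"):
        self.signature = signature
        self.endpoint = endpoint
        self.standardize = standardize
        self.ties = ties

    def fit(self, training: PatientCohort, y=None):
        self.signature_ = reweight_signature(
            self.signature, training,
            endpoint=self.endpoint, standardize=self.standardize, ties=self.ties,
        )
        return self

    def predict(self, expression: pd.DataFrame) -> pd.Series:
        if not hasattr(self, "signature_"):
            raise UnweightedSignatureError("call fit before predict")
        return compute_ri(self.signature_, expression)

    transform = predict


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------


def _covariate_frame(cohort: PatientCohort, assignment: RiskAssignment) -> pd.DataFrame:
    """Trial-report design matrix: resistant dummy, age, sex (female ref), ISS (I ref)."""
    clin = cohort.clinical
    return pd.DataFrame(
        {
            "resistant": assignment.resistant_indicator,
            "age": clin["age"].to_numpy(),
            "sex_male": (clin["sex"] == "male").to_numpy().astype(float),
            "iss_II": (clin["iss"] == "II").to_numpy().astype(float),
            "iss_III": (clin["iss"] == "III").to_numpy().astype(float),
        },
        index=clin.index,
    )


@dataclasses.dataclass
class EndpointEvaluation:
    """Evaluation bundle for one endpoint (PFS or OS)."""

    endpoint: str
    km_by_stratum: dict[str, KMCurve]
    medians: dict[str, float]
    logrank: LogRankResult
    cox_univariate: CoxPH
    cox_multivariate: CoxPH
    rcs: Optional[RCSCurve]
    roc: dict[float, TdROC]

    @property
    def univariate_hr(self) -> float:
        return float(self.cox_univariate.hazard_ratios_[0])

    @property
    def univariate_p(self) -> float:
        return float(self.cox_univariate.wald_p_[0])

    @property
    def multivariate_p(self) -> float:
        return float(self.cox_multivariate.wald_p_[0])


@dataclasses.dataclass
class CohortEvaluation:
    pfs: EndpointEvaluation
    os: EndpointEvaluation
    alpha: float = 0.05


def _evaluate_endpoint(cohort: PatientCohort, assignment: RiskAssignment,
                       endpoint: str, horizons, alpha: float,
                       with_rcs: bool = True) -> EndpointEvaluation:
    time, event = cohort.endpoint(endpoint)
    surv = SurvivalData(time, event)
    strata = assignment.stratum.to_numpy()

    km = {}
    medians = {}
    for s in STRATA:
        mask = strata == s
        if mask.any():
            curve = km_estimate(SurvivalData(time[mask], event[mask]), alpha=alpha)
            km[s] = curve
            medians[s] = curve.median
    lr = logrank_test(surv, strata)

    X = _covariate_frame(cohort, assignment)
    cox_uni = CoxPH(alpha=alpha).fit(X[["resistant"]], surv)
    cox_multi = CoxPH(alpha=alpha).fit(X, surv)

    rcs = rcs_loghazard(assignment.ri.to_numpy(), surv, alpha=alpha) \
        if with_rcs else None

    roc = {}
    for h in horizons:
        if surv.time.min() <= h <= surv.time.max() and \
                ((surv.event == 1) & (surv.time <= h)).any():
            try:
                roc[float(h)] = td_roc(assignment.ri.to_numpy(), surv, h)
            except Exception:
                continue
    return EndpointEvaluation(
        endpoint=endpoint, km_by_stratum=km, medians=medians, logrank=lr,
        cox_univariate=cox_uni, cox_multivariate=cox_multi, rcs=rcs, roc=roc,
    )


def evaluate_cohort(cohort: PatientCohort, assignment: RiskAssignment,
                    horizons=(12.0, 24.0, 36.0), alpha: float = 0.05,
                    with_rcs: bool = True) -> CohortEvaluation:
    """Full clinical evaluation of an RI assignment on a cohort.

    For both PFS and OS: per-stratum Kaplan-Meier curves and medians with a
    three-group log-rank test; univariate Cox of the merged resistant
    dichotomy; a multivariate Cox adding age, sex (female reference) and
    ISS stage dummies (stage I reference); a restricted-cubic-spline log
    relative-hazard curve in the RI; and time-dependent ROC at the
    requested horizons (months).
    """
    if len(assignment.frame) != cohort.n_patients:
        raise ValueError("assignment and cohort sizes differ")
    return CohortEvaluation(
        pfs=_evaluate_endpoint(cohort, assignment, "pfs", horizons, alpha, with_rcs),
        os=_evaluate_endpoint(cohort, assignment, "os", horizons, alpha, with_rcs),
        alpha=alpha,
    )


_ROW_LABELS = {
    "age": "Age",
    "sex_male": "SexMale",
    "iss_II": "ISS2",
    "iss_III": "ISS3",
    "resistant": "RI(75,100]",
}


def hazard_ratio_report(cohort: PatientCohort, assignment: RiskAssignment,
                  endpoint: str = "pfs", alpha: float = 0.05) -> pd.DataFrame:
    """Hazard-ratio report for one endpoint in the trial-table layout.

    Univariate columns come from separate Cox fits (age alone, sex alone,
    the two ISS dummies jointly, the resistant dummy alone); multivariate
    columns from the single adjusted model.  Each cell block is hazard
    ratio, 95% CI and Wald p-value.
    """
    time, event = cohort.endpoint(endpoint)
    surv = SurvivalData(time, event)
    X = _covariate_frame(cohort, assignment)

    uni: dict[str, tuple] = {}
    for cols in (["age"], ["sex_male"], ["iss_II", "iss_III"], ["resistant"]):
        fit = CoxPH(alpha=alpha).fit(X[cols], surv)
        for i, c in enumerate(cols):
            uni[c] = (fit.hazard_ratios_[i], *fit.hr_confint_[i], fit.wald_p_[i])
    multi_fit = CoxPH(alpha=alpha).fit(X, surv)

    rows = []
    for i, c in enumerate(X.columns):
        h, lo, hi, p = uni[c]
        rows.append(
            {
                "variable": _ROW_LABELS[c],
                "uni_hazard_ratio": h, "uni_ci_lower": lo, "uni_ci_upper": hi,
                "uni_p_value": p,
                "multi_hazard_ratio": multi_fit.hazard_ratios_[i],
                "multi_ci_lower": multi_fit.hr_confint_[i, 0],
                "multi_ci_upper": multi_fit.hr_confint_[i, 1],
                "multi_p_value": multi_fit.wald_p_[i],
            }
        )
    report = pd.DataFrame(rows).set_index("variable")
    report.attrs["endpoint"] = endpoint
    return report
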