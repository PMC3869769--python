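"""Random-gene-list permutation null and drug-specificity check.

A prognostic signature can look good by chance: many random gene lists
correlate spuriously with outcome.  This module repeats the full
reweight -> score -> stratify -> Cox pipeline for randomly drawn probe
lists of the same size as the true signature and reports the fraction of
lists whose merged-stratum Cox p-value (univariate and covariate-adjusted)
beats the true signature's.  A second check asks whether the winning
random lists actually track the drug phenotype: their list-weighted
cell-line scores are correlated against the panel's GI50, counting lists
with a significant Pearson correlation.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MelresError, MissingProbeError
from .index import compute_ri, reweight_signature, stratify, _covariate_frame
from .signature import GeneSignature
from .simulate import CellLinePanel, PatientCohort
from .survival import CoxPH, SurvivalData

__all__ = [
    "NullExperimentResult",
    "run_null_experiment",
    "GI50SpecificityResult",
    "gi50_specificity_check",
]

logger = logging.getLogger(__name__)


def _fit_and_test(probes: Sequence[str], training: PatientCohort,
                  validation: PatientCohort, endpoint: str = "pfs"):
    """Reweight a probe list on training PFS, score validation, return p-values."""
    sig = GeneSignature(pd.DataFrame({"probe_id": list(probes),
                                      "weight": 0.0}))
    reweighted = reweight_signature(sig, training, endpoint=endpoint)
    ri = compute_ri(reweighted, validation.expression)
    assignment = stratify(ri)
    time, event = validation.endpoint(endpoint)
    surv = SurvivalData(time, event)
    X = _covariate_frame(validation, assignment)
    uni_p = float(CoxPH().fit(X[["resistant"]], surv).wald_p_[0])
    multi_p = float(CoxPH().fit(X, surv).wald_p_[0])
    return uni_p, multi_p, reweighted


@dataclasses.dataclass
class NullExperimentResult:
    """Outcome of the random-list chance-performance experiment."""

    n_lists: int
    list_size: int
    seed: int
    per_list: pd.DataFrame  # list_id, probes, univariate_p, multivariate_p, failed
    signatures: list[Optional[GeneSignature]]
    true_signature: GeneSignature
    true_univariate_p: float
    true_multivariate_p: float
    n_failed: int

    @property
    def fraction_better_uni(self) -> float:
        ok = self.per_list.loc[~self.per_list["failed"]]
        return float((ok["univariate_p"] < self.true_univariate_p).mean())

    @property
    def fraction_better_multi(self) -> float:
        ok = self.per_list.loc[~self.per_list["failed"]]
        return float((ok["multivariate_p"] < self.true_multivariate_p).mean())

    def better_lists(self, kind: str = "univariate") -> list[GeneSignature]:
        """Reweighted signatures of the lists that beat the true signature."""
        col = f"{kind}_p"
        ref = self.true_univariate_p if kind == "univariate" else self.true_multivariate_p
        out = []
        for i, row in self.per_list.iterrows():
            if not row["failed"] and row[col] < ref:
                out.append(self.signatures[i])
        return out

    def summary(self) -> dict:
        return {
            "n_lists": self.n_lists,
            "list_size": self.list_size,
            "seed": self.seed,
            "n_failed": self.n_failed,
            "true_univariate_p": self.true_univariate_p,
            "true_multivariate_p": self.true_multivariate_p,
            "fraction_better_uni": self.fraction_better_uni,
            "fraction_better_multi": self.fraction_better_multi,
        }


def run_null_experiment(
    training: PatientCohort,
    validation: PatientCohort,
    true_signature: GeneSignature,
    n_lists: int = 200,
    list_size: int = 19,
    seed: int = 0,
    endpoint: str = "pfs",
) -> NullExperimentResult:
    """Compare the true signature against seeded random probe lists.

    Each list of ``list_size`` probes is drawn without replacement from the
    probe universe shared by both cohorts, then pushed through the same
    reweight/score/stratify/Cox pipeline as the true signature.  Lists
    whose Cox fits fail are recorded and excluded from the comparison
    denominator with a logged count.
    """
    universe = sorted(set(training.expression.index) & set(validation.expression.index))
    if list_size > len(universe):
        raise ValueError(
            f"list_size ({list_size}) exceeds shared probe universe ({len(universe)})"
        )
    missing = [p for p in true_signature.probe_ids if p not in set(universe)]
    if missing:
        raise MissingProbeError(missing)

    true_uni, true_multi, _ = _fit_and_test(
        true_signature.probe_ids, training, validation, endpoint
    )

    rng = np.random.default_rng(seed)
    universe_arr = np.asarray(universe, dtype=object)
    records = []
    signatures: list[Optional[GeneSignature]] = []
    n_failed = 0
    for i in range(n_lists):
        probes = rng.choice(universe_arr, size=list_size, replace=False)
        try:
            uni_p, multi_p, sig = _fit_and_test(probes, training, validation, endpoint)
            failed = False
        except MelresError:
            uni_p = multi_p = float("nan")
            sig = None
            failed = True
            n_failed += 1
        records.append(
            {
                "list_id": i,
                "probes": ";".join(map(str, probes)),
                "univariate_p": uni_p,
                "multivariate_p": multi_p,
                "failed": failed,
            }
        )
        signatures.append(sig)
    if n_failed:
        logger.warning("%d of %d random lists failed to fit and were excluded",
                       n_failed, n_lists)
    per_list = pd.DataFrame.from_records(records)
    return NullExperimentResult(
        n_lists=n_lists, list_size=list_size, seed=seed,
        per_list=per_list, signatures=signatures,
        true_signature=true_signature,
        true_univariate_p=true_uni, true_multivariate_p=true_multi,
        n_failed=n_failed,
    )


@dataclasses.dataclass
class GI50SpecificityResult:
    """Per-list Pearson correlation of list-weighted scores with GI50."""

    n_significant: int
    alpha: float
    table: pd.DataFrame  # list index, correlation, p_value, significant


def gi50_specificity_check(
    lists: Sequence[GeneSignature],
    panel: CellLinePanel,
    alpha: float = 0.05,
) -> GI50SpecificityResult:
    """Count random lists whose cell-line scores correlate with GI50.

    For each reweighted list the per-line score is ``new_weights .
    expression``; the two-sided Pearson correlation with the panel's GI50
    is computed and lists with p < alpha are counted.  Lists that carry
    genuinely drug-related probes should correlate; spuriously prognostic
    lists should be calibrated at the alpha level.
    """
    rows = []
    n_sig = 0
    for i, sig in enumerate(lists):
        ri = compute_ri(sig, panel.expression)
        gi = panel.gi50.to_numpy()
        if np.ptp(ri.to_numpy()) == 0 or np.ptp(gi) == 0:
            r, p = float("nan"), 1.0
        else:
            r, p = stats.pearsonr(ri.to_numpy(), gi)
        significant = bool(p < alpha)
        n_sig += significant
        rows.append({"list_index": i, "correlation": float(r),
                     "p_value": float(p), "significant": significant})
    table = pd.DataFrame.from_records(
        rows, columns=["list_index", "correlation", "p_value", "significant"]
    )
    return GI50SpecificityResult(n_significant=n_sig, alpha=alpha, table=table)
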