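"""Synthetic cell-line panels and trial cohorts.

The generators produce data with exactly the statistical structure the
pipeline assumes, so every downstream stage is testable without any
external download:

* a cell-line panel whose log-GI50 depends linearly on a sparse planted set
  of probes plus Gaussian noise (the in-vitro drug-screen substrate);
* patient cohorts whose progression-free and overall survival hazards are
  log-linear in the same planted probes (exponential baseline, proportional
  hazards, independent exponential censoring), with clinical covariates
  (age, sex, ISS stage) drawn independently of expression;
* a negative-control mode (``null_mode``) in which the hazard is
  independent of expression, emulating a cohort treated without the index
  drug.

Default sizes mirror the study design the pipeline targets: an 18-line
panel, a 94-patient training trial, a 263-patient validation trial, a
19-probe planted resistance support, and months as the time unit.
All randomness flows from ``SimulationConfig.seed``; identical
seed + config gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError

__all__ = [
    "SimulationConfig",
    "CellLinePanel",
    "PatientCohort",
    "simulate_cell_line_panel",
    "simulate_cohort",
]

# per-month defaults: ln(2)/27 gives a ~27-month median PFS at baseline,
# matching the order of magnitude seen in transplant-eligible myeloma trials
_DEFAULT_HAZARD = np.log(2.0) / 27.0

_ISS_PROBS = (0.39, 0.36, 0.25)
_ISS_LEVELS = ("I", "II", "III")
_MALE_PROB = 0.55
_AGE_RANGE = (35.0, 69.0)
_OS_SCALE = 0.5  # OS hazard rate and linear predictor both scaled by this


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generators.

    Parameters
    ----------
    n_probes, n_lines, n_patients : int
        Dimensions of the expression matrices.
    support_size : int
        Number of planted resistance probes (GI50 and hazard effects).
    effect_scale : float
        Magnitude of the planted per-probe effects; signs alternate.
    baseline_hazard_rate : float
        PFS event hazard per month at linear predictor 0 (> 0).
    censoring_rate : float
        Independent exponential censoring hazard per month (0 = none).
    noise_sd : float
        Residual standard deviation of the GI50 regression.
    seed : int
        Root seed; the panel and cohort generators derive disjoint streams.
    """

    n_probes: int = 1000
    n_lines: int = 18
    n_patients: int = 263
    support_size: int = 19
    effect_scale: float = 0.5
    baseline_hazard_rate: float = _DEFAULT_HAZARD
    censoring_rate: float = 0.02
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_probes < 1 or self.n_lines < 1 or self.n_patients < 1:
            raise InvalidConfigError("dimensions must be positive integers")
        if self.support_size < 0:
            raise InvalidConfigError("support_size must be non-negative")
        if self.support_size > self.n_probes:
            raise InvalidConfigError(
                f"support_size ({self.support_size}) exceeds n_probes ({self.n_probes})"
            )
        if self.effect_scale < 0:
            raise InvalidConfigError("effect_scale must be >= 0")
        if self.baseline_hazard_rate <= 0:
            raise InvalidConfigError("baseline_hazard_rate must be > 0")
        if self.censoring_rate < 0:
            raise InvalidConfigError("censoring_rate must be >= 0")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")


def _probe_ids(n: int) -> list[str]:
    # fixed-width numeric prefix keeps lexical and positional order aligned
    return [f"{100000 + i}_at" for i in range(n)]


def _planted_weights(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    w = np.zeros(config.n_probes)
    if config.support_size > 0:
        support = np.sort(
            rng.choice(config.n_probes, size=config.support_size, replace=False)
        )
        signs = (-1.0) ** np.arange(config.support_size)
        w[support] = config.effect_scale * signs
    return w


@dataclasses.dataclass
class CellLinePanel:
    """Expression (probes x lines, log scale) with per-line log-GI50."""

    expression: pd.DataFrame
    gi50: pd.Series
    true_weights: pd.Series
    intercept: float = 0.0

    def __post_init__(self):
        if len(self.gi50) != self.expression.shape[1]:
            raise ValueError("gi50 length must equal the number of cell lines")
        if self.expression.isna().any().any():
            raise ValueError("expression must have no missing values")
        if len(self.true_weights) != self.expression.shape[0]:
            raise ValueError("true_weights must have one entry per probe")

    @property
    def n_lines(self) -> int:
        return self.expression.shape[1]

    @property
    def n_probes(self) -> int:
        return self.expression.shape[0]


@dataclasses.dataclass
class PatientCohort:
    """Expression (probes x patients) with survival endpoints and covariates.

    ``clinical`` is indexed by sample id (the expression column names) with
    columns pfs_months, pfs_event, os_months, os_event, age, sex, iss.
    """

    expression: pd.DataFrame
    clinical: pd.DataFrame
    true_weights: Optional[pd.Series] = None
    label: str = "cohort"

    def __post_init__(self):
        if list(self.clinical.index) != list(self.expression.columns):
            raise ValueError(
                "clinical sample ids must exactly match expression column names"
            )
        required = {"pfs_months", "pfs_event", "os_months", "os_event",
                    "age", "sex", "iss"}
        missing = required - set(self.clinical.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        for col in ("pfs_event", "os_event"):
            if not self.clinical[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be 0/1")
        for col in ("pfs_months", "os_months"):
            if (self.clinical[col] <= 0).any():
                raise ValueError(f"{col} must be strictly positive")
        if not self.clinical["sex"].isin(["female", "male"]).all():
            raise ValueError("sex must be 'female' or 'male'")
        if not self.clinical["iss"].isin(list(_ISS_LEVELS)).all():
            raise ValueError("iss must be one of I, II, III")

    @property
    def n_patients(self) -> int:
        return self.expression.shape[1]

    @property
    def pfs(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.clinical["pfs_months"].to_numpy(),
                self.clinical["pfs_event"].to_numpy())

    @property
    def os(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.clinical["os_months"].to_numpy(),
                self.clinical["os_event"].to_numpy())

    def endpoint(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        name = name.lower()
        if name == "pfs":
            return self.pfs
        if name == "os":
            return self.os
        raise ValueError("endpoint must be 'pfs' or 'os'")


def simulate_cell_line_panel(config: SimulationConfig) -> CellLinePanel:
    """Simulate an in-vitro panel whose GI50 is sparse-linear in expression.

    Expression entries are i.i.d. standard normal on the log scale; the
    planted support carries alternating-sign weights of magnitude
    ``effect_scale``; ``gi50 = intercept + w.x + N(0, noise_sd)`` with the
    intercept fixed at 0 (log-concentration units are arbitrary).
    """
    rng = np.random.default_rng([config.seed, 0])
    w = _planted_weights(config, rng)
    X = rng.standard_normal((config.n_probes, config.n_lines))
    noise = rng.normal(0.0, config.noise_sd, size=config.n_lines) \
        if config.noise_sd > 0 else np.zeros(config.n_lines)
    gi50 = w @ X + noise
    probes = _probe_ids(config.n_probes)
    lines = [f"CL{i + 1:02d}" for i in range(config.n_lines)]
    return CellLinePanel(
        expression=pd.DataFrame(X, index=probes, columns=lines),
        gi50=pd.Series(gi50, index=lines, name="gi50"),
        true_weights=pd.Series(w, index=probes, name="true_weight"),
        intercept=0.0,
    )


def simulate_cohort(
    config: SimulationConfig,
    true_weights,
    null_mode: bool = False,
    correlated_iss: bool = False,
    label: str = "cohort",
) -> PatientCohort:
    """Simulate a trial cohort under proportional hazards.

    The PFS hazard is ``baseline_hazard_rate * exp(eta)`` with
    ``eta = true_weights . x`` per patient (``eta = 0`` in ``null_mode``);
    OS uses the rate and linear predictor both scaled by 0.5 so the two
    endpoints agree in effect direction.  Censoring is independent
    exponential at ``censoring_rate`` for both endpoints.  Age, sex and ISS
    are drawn independently of expression unless ``correlated_iss`` links
    ISS stage to the hazard's linear predictor for robustness scenarios.
    """
    w = np.asarray(true_weights, dtype=float)
    if len(w) != config.n_probes:
        raise ValueError(
            f"true_weights length ({len(w)}) must equal n_probes ({config.n_probes})"
        )
    rng = np.random.default_rng([config.seed, 1])
    n = config.n_patients
    X = rng.standard_normal((config.n_probes, n))
    eta = np.zeros(n) if null_mode else w @ X

    def draw_endpoint(rate: float, lin: np.ndarray):
        t_event = rng.exponential(1.0 / (rate * np.exp(lin)))
        if config.censoring_rate > 0:
            t_cens = rng.exponential(1.0 / config.censoring_rate, size=n)
        else:
            t_cens = np.full(n, np.inf)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        return time, event

    pfs_time, pfs_event = draw_endpoint(config.baseline_hazard_rate, eta)
    os_time, os_event = draw_endpoint(
        _OS_SCALE * config.baseline_hazard_rate, _OS_SCALE * eta
    )

    age = rng.uniform(*_AGE_RANGE, size=n)
    sex = np.where(rng.random(n) < _MALE_PROB, "male", "female")
    if correlated_iss:
        # upper linear-predictor tertile skews toward stage III
        cut = np.quantile(eta, 2.0 / 3.0) if not null_mode else np.inf
        iss = np.array([
            rng.choice(_ISS_LEVELS, p=(0.2, 0.3, 0.5)) if e > cut
            else rng.choice(_ISS_LEVELS, p=_ISS_PROBS)
            for e in eta
        ])
    else:
        iss = rng.choice(_ISS_LEVELS, size=n, p=_ISS_PROBS)

    probes = _probe_ids(config.n_probes)
    samples = [f"S{i + 1:04d}" for i in range(n)]
    clinical = pd.DataFrame(
        {
            "pfs_months": pfs_time,
            "pfs_event": pfs_event,
            "os_months": os_time,
            "os_event": os_event,
            "age": age,
            "sex": sex,
            "iss": iss,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return PatientCohort(
        expression=pd.DataFrame(X, index=probes, columns=samples),
        clinical=clinical,
        true_weights=None if null_mode else pd.Series(w, index=probes,
                                                      name="true_weight"),
        label=label,
    )
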