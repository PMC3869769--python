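"""Sparse partial least squares discovery of drug-resistance candidates.

Regresses the cell-line GI50 readout on log-scale expression with the
threshold-and-refit SPLS scheme: at each of ``K`` steps the covariance
direction ``Z = X'r`` of the current residual is soft-thresholded
componentwise at ``eta * max|Z|``, the surviving probes join the active
set, and an ordinary PLS (NIPALS) regression restricted to the active set
is refitted before deflation.  ``eta`` in [0, 1) controls sparsity
(``eta = 0`` recovers standard PLS); coefficients are reported on the
original expression scale.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .exceptions import DegenerateResponseError, EmptySignatureError
from .signature import GeneSignature
from .simulate import CellLinePanel

__all__ = ["SPLSConfig", "SparsePLS", "fit_spls", "tune_spls", "select_signature"]


@dataclasses.dataclass(frozen=True)
class SPLSConfig:
    """Tuning parameters for the sparse PLS fit."""

    eta: float = 0.5
    n_components: int = 2
    cv_folds: int = 5
    seed: int = 0
    cv_mspe: float = float("nan")  # filled in by tune_spls

    def __post_init__(self):
        if not 0.0 <= self.eta < 1.0:
            raise ValueError("eta must lie in [0, 1)")
        if self.n_components < 1:
            raise ValueError("n_components must be a positive integer")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


class SparsePLS(RegressorMixin, BaseEstimator):
    """Sparse PLS regression (threshold-and-refit variant).

    Parameters
    ----------
    eta : float in [0, 1)
        Sparsity threshold fraction; direction entries below
        ``eta * max|X'r|`` in magnitude are zeroed.
    n_components : int
        Number of latent components K (capped at the data rank with a
        warning).
    scale : bool
        Standardise columns to unit variance before fitting (recommended:
        microarray probes have heterogeneous variances).  Coefficients are
        always mapped back to the original scale.

    Attributes
    ----------
    coef_ : ndarray (p,)
        Regression coefficients on the original scale (zero off-support).
    intercept_ : float
    support_ : ndarray of int
        Indices of the active set, in increasing order.
    n_components_used_ : int
    """

    def __init__(self, eta: float = 0.5, n_components: int = 2, scale: bool = True):
        self.eta = eta
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y):
        if not 0.0 <= self.eta < 1.0:
            raise ValueError("eta must lie in [0, 1)")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y have incompatible shapes")
        if n < 3:
            raise ValueError("at least 3 samples are required")
        if np.ptp(y) == 0:
            raise DegenerateResponseError("response is constant; nothing to fit")

        x_mean = X.mean(axis=0)
        if self.scale:
            x_scale = X.std(axis=0, ddof=1)
            x_scale[x_scale == 0] = 1.0
        else:
            x_scale = np.ones(p)
        Xc = (X - x_mean) / x_scale
        y_mean = y.mean()
        yc = y - y_mean

        K = self.n_components
        max_K = min(n - 1, p)
        if K > max_K:
            warnings.warn(
                f"n_components reduced from {K} to {max_K} (data rank limit)",
                UserWarning,
            )
            K = max_K

        active: np.ndarray = np.array([], dtype=int)
        beta_scaled = np.zeros(p)
        n_used = 0
        r = yc
        for k in range(1, K + 1):
            Z = Xc.T @ r
            zmax = np.abs(Z).max()
            if zmax <= 0:
                break  # residual orthogonal to all probes; no further direction
            thr = self.eta * zmax
            w = np.sign(Z) * np.maximum(np.abs(Z) - thr, 0.0)
            new = np.flatnonzero(w)
            active = np.union1d(active, new)
            if len(active) == 0:
                break
            ncomp = min(k, len(active), n - 1)
            pls = PLSRegression(n_components=ncomp, scale=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pls.fit(Xc[:, active], yc)
            beta_scaled = np.zeros(p)
            beta_scaled[active] = pls.coef_.ravel()
            n_used = ncomp
            r = yc - Xc[:, active] @ beta_scaled[active]

        self.coef_ = beta_scaled / x_scale
        self.intercept_ = float(y_mean - self.coef_ @ x_mean)
        self.support_ = active
        self.n_components_used_ = n_used
        self.n_features_in_ = p
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_


def fit_spls(panel: CellLinePanel, config: SPLSConfig | None = None,
             **kwargs) -> SparsePLS:
    """Fit sparse PLS of GI50 on a cell-line panel's expression.

    The fitted estimator additionally carries ``probe_ids_`` (row index of
    the panel) and ``cv_mspe_`` (from the config, NaN unless tuned).
    """
    if config is None:
        config = SPLSConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or keyword overrides, not both")
    model = SparsePLS(eta=config.eta, n_components=config.n_components)
    model.fit(panel.expression.to_numpy().T, panel.gi50.to_numpy())
    model.probe_ids_ = list(panel.expression.index)
    model.cv_mspe_ = config.cv_mspe
    return model


def tune_spls(panel: CellLinePanel, eta_grid, k_grid,
              cv_folds: int = 5, seed: int = 0) -> SPLSConfig:
    """Choose (eta, K) by cross-validated mean squared prediction error.

    Folds are formed by seeded shuffling; ties are broken toward larger
    eta, then smaller K (sparser, simpler models).
    """
    eta_grid = list(eta_grid)
    k_grid = list(k_grid)
    if not eta_grid or not k_grid:
        raise ValueError("tuning grids must be non-empty")
    n = panel.n_lines
    if n < cv_folds:
        raise ValueError(f"fewer cell lines ({n}) than folds ({cv_folds})")
    X = panel.expression.to_numpy().T
    y = panel.gi50.to_numpy()
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    best = None
    for eta in eta_grid:
        for K in k_grid:
            sse, cnt = 0.0, 0
            for train, test in splits:
                model = SparsePLS(eta=eta, n_components=K)
                model.fit(X[train], y[train])
                resid = y[test] - model.predict(X[test])
                sse += float(resid @ resid)
                cnt += len(test)
            mspe = sse / cnt
            key = (mspe, -eta, K)
            if best is None or key < best[0]:
                best = (key, eta, K, mspe)
    _, eta, K, mspe = best
    return SPLSConfig(eta=eta, n_components=K, cv_folds=cv_folds,
                      seed=seed, cv_mspe=mspe)


def select_signature(model: SparsePLS, max_size: int | None = None) -> GeneSignature:
    """Turn a fitted SPLS model's support into a discovery-stage signature.

    Probes are ranked by absolute coefficient (descending) when truncating
    to ``max_size``; exact ties break by probe-id lexical order.  The
    signature's ``weight`` column holds the SPLS coefficient; ``new_weight``
    is left unset for the reweighting stage.
    """
    if not hasattr(model, "coef_"):
        raise ValueError("model must be fitted before selecting a signature")
    probe_ids = getattr(model, "probe_ids_", None)
    if probe_ids is None:
        probe_ids = [f"probe{i}" for i in range(len(model.coef_))]
    support = model.support_
    if len(support) == 0:
        raise EmptySignatureError("SPLS support is empty; no signature to select")
    rows = sorted(
        ((probe_ids[i], model.coef_[i]) for i in support),
        key=lambda r: (-abs(r[1]), r[0]),
    )
    if max_size is not None:
        rows = rows[:max_size]
    frame = pd.DataFrame(
        {"probe_id": [r[0] for r in rows], "weight": [r[1] for r in rows]}
    )
    # keep deterministic probe-id order within the signature file
    frame = frame.sort_values("probe_id", kind="mergesort").reset_index(drop=True)
    return GeneSignature(frame)
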