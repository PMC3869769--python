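"""Survival-analysis core used by every evaluation stage of the pipeline.

Implements, from first principles:

* Cox proportional-hazards regression — Newton-Raphson maximisation of the
  partial likelihood with Efron's correction for tied event times (Breslow
  available via ``ties="breslow"``), observed-information covariance, Wald
  confidence intervals and p-values, and an Efron-consistent baseline
  cumulative hazard;
* the Kaplan-Meier product-limit estimator with Greenwood variance and a
  log(-log)-transformed confidence band for the median;
* the K-sample log-rank test (observed minus expected event counts with
  hypergeometric variance);
* Harrell's restricted cubic spline basis and log relative-hazard curves
  (Cox fit on the spline basis, likelihood-ratio association test, delta-
  method pointwise bands, curve centred at the median of the marker);
* cumulative-case / dynamic-control time-dependent ROC curves with
  Kaplan-Meier handling of censoring;
* martingale residuals.

All times are in months.  Survival data are right-censored pairs
``(time, event)`` with ``event`` 1 for an observed event and 0 for
censoring.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    ConvergenceError,
    DegenerateCovariateError,
    UndefinedROCError,
)

__all__ = [
    "SurvivalData",
    "as_survival_data",
    "CoxPH",
    "fit_cox",
    "KMCurve",
    "km_estimate",
    "LogRankResult",
    "logrank_test",
    "default_rcs_knots",
    "rcs_basis",
    "RCSCurve",
    "rcs_loghazard",
    "TdROC",
    "td_roc",
    "martingale_residuals",
]


# ---------------------------------------------------------------------------
# survival data container
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SurvivalData:
    """Right-censored survival times (months) with 0/1 event indicators."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or event.ndim != 1 or len(time) != len(event):
            raise ValueError("time and event must be 1-d arrays of equal length")
        if not np.isfinite(time).all():
            raise ValueError("survival times must be finite")
        if (time <= 0).any():
            raise ValueError("survival times must be strictly positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(int))

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def as_survival_data(y) -> SurvivalData:
    """Coerce ``y`` to :class:`SurvivalData`.

    Accepts a SurvivalData, a ``(time, event)`` tuple, a 2-column array,
    a structured array with ``time``/``event`` fields, or a DataFrame with
    such columns.
    """
    if isinstance(y, SurvivalData):
        return y
    if isinstance(y, pd.DataFrame):
        return SurvivalData(y["time"].to_numpy(), y["event"].to_numpy())
    if isinstance(y, np.ndarray) and y.dtype.names:
        return SurvivalData(y["time"], y["event"])
    if isinstance(y, (tuple, list)) and len(y) == 2:
        return SurvivalData(np.asarray(y[0]), np.asarray(y[1]))
    arr = np.asarray(y)
    if arr.ndim == 2 and arr.shape[1] == 2:
        return SurvivalData(arr[:, 0], arr[:, 1])
    raise TypeError("cannot interpret y as survival data")


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def _check_covariates(X):
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{i}" for i in range(arr.shape[1])]
    if arr.ndim != 2:
        raise ValueError("covariates must be a 2-d array")
    if not np.isfinite(arr).all():
        raise ValueError("covariates must be finite")
    return arr, names


class CoxPH(BaseEstimator):
    """Cox proportional-hazards regression.

    Maximises the partial log-likelihood by Newton-Raphson with
    step-halving; convergence when the relative log-likelihood change
    drops below ``tol`` (default 1e-9) within ``max_iter`` iterations.
    Tied event times are handled by Efron's correction by default.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : ndarray of shape (p,)
        Log hazard ratios.
    covariance_ : ndarray of shape (p, p)
        Inverse observed information.
    se_, hazard_ratios_, hr_confint_, wald_p_ : per-covariate summaries.
    loglik_, loglik_null_ : fitted and null partial log-likelihoods.
    linear_predictor_ : ndarray of shape (n,)
        ``X @ coef_`` in the input row order.
    baseline_event_times_, baseline_cumhaz_ : Efron/Breslow baseline
        cumulative hazard evaluated at the distinct event times.
    """

    def __init__(self, ties: str = "efron", alpha: float = 0.05,
                 tol: float = 1e-9, max_iter: int = 25):
        self.ties = ties
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter

    # -- partial likelihood machinery -----------------------------------

    def _prepare(self, X, surv):
        order = np.argsort(surv.time, kind="mergesort")
        ts = surv.time[order]
        ev = surv.event[order].astype(bool)
        Xs = X[order]
        uniq, first, inv = np.unique(ts, return_index=True, return_inverse=True)
        d = np.bincount(inv[ev], minlength=len(uniq))
        ev_idx = np.flatnonzero(ev)
        grp = inv[ev_idx]
        singles = ev_idx[d[grp] == 1]
        multi_groups = np.flatnonzero(d >= 2)
        multi_rows = {g: ev_idx[grp == g] for g in multi_groups}
        return {
            "order": order, "ts": ts, "ev": ev, "Xs": Xs, "uniq": uniq,
            "first": first, "d": d, "singles": singles,
            "f_singles": first[inv[singles]], "multi_groups": multi_groups,
            "multi_rows": multi_rows,
        }

    def _loglik_only(self, beta, S):
        Xs = S["Xs"]
        eta = Xs @ beta
        if not np.isfinite(eta).all() or np.abs(eta).max() > 500:
            return -np.inf
        theta = np.exp(eta)
        r0 = np.cumsum(theta[::-1])[::-1]
        efron = self.ties == "efron"
        singles, f_singles = S["singles"], S["f_singles"]
        ll = eta[singles].sum() - np.log(r0[f_singles]).sum()
        for g in S["multi_groups"]:
            rows = S["multi_rows"][g]
            f = S["first"][g]
            dd = S["d"][g]
            td0 = theta[rows].sum()
            ll += eta[rows].sum()
            fracs = np.arange(dd) / dd if efron else np.zeros(dd)
            ll -= np.log(r0[f] - fracs * td0).sum()
        return ll

    def _loglik_grad_info(self, beta, S):
        Xs = S["Xs"]
        p = Xs.shape[1]
        eta = Xs @ beta
        theta = np.exp(eta)
        wX = theta[:, None] * Xs
        r0 = np.cumsum(theta[::-1])[::-1]
        r1 = np.cumsum(wX[::-1], axis=0)[::-1]
        wXX = np.einsum("n,ni,nj->nij", theta, Xs, Xs)
        r2 = np.cumsum(wXX[::-1], axis=0)[::-1]
        efron = self.ties == "efron"

        singles, f_singles = S["singles"], S["f_singles"]
        ll = eta[singles].sum() - np.log(r0[f_singles]).sum()
        z = r1[f_singles] / r0[f_singles, None]
        grad = Xs[singles].sum(axis=0) - z.sum(axis=0)
        info = (r2[f_singles] / r0[f_singles, None, None]).sum(axis=0)
        info -= np.einsum("ni,nj->ij", z, z)

        for g in S["multi_groups"]:
            rows = S["multi_rows"][g]
            f = S["first"][g]
            dd = S["d"][g]
            s0, s1, s2 = r0[f], r1[f], r2[f]
            td0 = theta[rows].sum()
            td1 = wX[rows].sum(axis=0)
            td2 = wXX[rows].sum(axis=0)
            ll += eta[rows].sum()
            grad += Xs[rows].sum(axis=0)
            fracs = np.arange(dd) / dd if efron else np.zeros(dd)
            for fr in fracs:
                den = s0 - fr * td0
                zz = (s1 - fr * td1) / den
                ll -= np.log(den)
                grad -= zz
                info += (s2 - fr * td2) / den - np.outer(zz, zz)
        if p == 0:
            info = np.zeros((0, 0))
        return ll, grad, info

    def _baseline(self, beta, S):
        """Cumulative baseline hazard increments at distinct event times."""
        theta = np.exp(S["Xs"] @ beta)
        r0 = np.cumsum(theta[::-1])[::-1]
        efron = self.ties == "efron"
        event_groups = np.flatnonzero(S["d"] > 0)
        times = S["uniq"][event_groups]
        inc = np.empty(len(event_groups))
        ev = S["ev"]
        for i, g in enumerate(event_groups):
            f = S["first"][g]
            dd = S["d"][g]
            if dd == 1 or not efron:
                inc[i] = dd / r0[f]
            else:
                rows = S["multi_rows"][g]
                td0 = theta[rows].sum()
                fracs = np.arange(dd) / dd
                inc[i] = np.sum(1.0 / (r0[f] - fracs * td0))
        _ = ev  # events enter via d; kept for clarity
        return times, np.cumsum(inc)

    # -- public API ------------------------------------------------------

    def fit(self, X, y):
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        X, names = _check_covariates(X)
        surv = as_survival_data(y)
        if len(X) != surv.n:
            raise ValueError("covariates and survival data have different lengths")
        if surv.n_events < 1:
            raise ValueError("at least one event is required")
        spans = np.ptp(X, axis=0)
        if (spans == 0).any():
            bad = [names[i] for i in np.flatnonzero(spans == 0)]
            raise DegenerateCovariateError(
                f"constant covariate column(s): {', '.join(bad)}"
            )
        p = X.shape[1]
        S = self._prepare(X, surv)

        beta = np.zeros(p)
        ll, grad, info = self._loglik_grad_info(beta, S)
        self.loglik_null_ = ll
        converged = p == 0  # covariate-free model: baseline hazard only
        n_iter = 0
        for _ in range(self.max_iter if p else 0):
            n_iter += 1
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}") from exc
            t = 1.0
            accepted = False
            for _ in range(40):
                cand = beta + t * step
                llc = self._loglik_only(cand, S)
                if np.isfinite(llc) and llc >= ll - 1e-12 * (abs(ll) + 1.0):
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                raise ConvergenceError("step-halving failed to improve the partial likelihood")
            beta = cand
            ll_new, grad, info = self._loglik_grad_info(beta, S)
            if abs(ll_new - ll) < self.tol * (abs(ll_new) + 1.0):
                # one polishing step: quadratic convergence makes the
                # remaining coefficient error negligible
                try:
                    beta = beta + np.linalg.solve(info, grad)
                except np.linalg.LinAlgError:
                    pass
                ll, grad, info = self._loglik_grad_info(beta, S)
                converged = True
                break
            ll = ll_new
        if not converged:
            raise ConvergenceError(
                "Newton-Raphson did not converge within "
                f"{self.max_iter} iterations (possible monotone likelihood / "
                "perfect separation)"
            )
        if p and np.abs(S["Xs"] @ beta).max() > 25:
            raise ConvergenceError(
                "diverging linear predictor: monotone partial likelihood "
                "(perfect separation)"
            )

        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular information at optimum: {exc}") from exc

        z = stats.norm.ppf(1.0 - self.alpha / 2.0)
        se = np.sqrt(np.diag(cov))
        self.coef_ = beta
        self.covariance_ = cov
        self.se_ = se
        self.hazard_ratios_ = np.exp(beta)
        self.hr_confint_ = np.column_stack(
            [np.exp(beta - z * se), np.exp(beta + z * se)]
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            zstat = np.where(se > 0, beta / se, np.inf)
        self.wald_p_ = 2.0 * stats.norm.sf(np.abs(zstat))
        self.loglik_ = ll
        self.linear_predictor_ = X @ beta
        self.n_events_ = surv.n_events
        self.n_iter_ = n_iter
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.n_features_in_ = p
        times, cumhaz = self._baseline(beta, S)
        self.baseline_event_times_ = times
        self.baseline_cumhaz_ = cumhaz
        self._surv = surv
        return self

    def predict(self, X):
        """Linear predictor (log relative hazard) for new covariates."""
        arr, _ = _check_covariates(X)
        return arr @ self.coef_

    def cumulative_hazard_at(self, times) -> np.ndarray:
        """Baseline cumulative hazard step function evaluated at ``times``."""
        idx = np.searchsorted(self.baseline_event_times_, np.asarray(times, float),
                              side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz_])
        return padded[idx]

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef_,
                "hazard_ratio": self.hazard_ratios_,
                "hr_lower": self.hr_confint_[:, 0],
                "hr_upper": self.hr_confint_[:, 1],
                "se": self.se_,
                "p": self.wald_p_,
            },
            index=self.feature_names_in_,
        )


def fit_cox(covariates, surv, ties: str = "efron", **kwargs) -> CoxPH:
    """Fit a Cox model; thin functional wrapper over :class:`CoxPH`."""
    return CoxPH(ties=ties, **kwargs).fit(covariates, surv)


def martingale_residuals(fit: CoxPH, surv=None) -> np.ndarray:
    """Per-subject martingale residuals of a fitted Cox model.

    ``event_i - H0(t_i) * exp(linear predictor_i)`` with the baseline
    cumulative hazard stored on the fit.  Returned in the row order of the
    data the model was fitted on.
    """
    data = fit._surv if surv is None else as_survival_data(surv)
    H = fit.cumulative_hazard_at(data.time)
    return data.event - H * np.exp(fit.linear_predictor_)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class KMCurve:
    """Product-limit survival curve at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float
    median_ci: tuple[float, float]
    n: int
    n_events: int

    def survival_at(self, t) -> np.ndarray:
        """Step-function evaluation; S(t)=1 before the first event."""
        idx = np.searchsorted(self.event_times, np.asarray(t, float), side="right")
        padded = np.concatenate([[1.0], self.survival])
        return padded[idx]


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> float:
    below = values <= level
    if not below.any():
        return float("nan")
    return float(times[np.argmax(below)])


def km_estimate(surv, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood variance and log(-log) CIs.

    The median and its confidence limits are read off where the curve and
    its log(-log)-transformed band first drop to 0.5; they are NaN when the
    corresponding curve never reaches 0.5.
    """
    surv = as_survival_data(surv)
    if surv.n < 1:
        raise ValueError("at least one subject required")
    order = np.argsort(surv.time, kind="mergesort")
    t = surv.time[order]
    e = surv.event[order]
    uniq, inv = np.unique(t, return_inverse=True)
    d = np.bincount(inv, weights=e.astype(float))
    removed = np.bincount(inv).astype(float)
    at_risk = surv.n - np.concatenate([[0.0], np.cumsum(removed)[:-1]])
    has_event = d > 0
    times = uniq[has_event]
    dj = d[has_event]
    nj = at_risk[has_event]
    S = np.cumprod(1.0 - dj / nj)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_term = np.cumsum(dj / (nj * (nj - dj)))
        var = np.where(S > 0, S**2 * gw_term, 0.0)
    se = np.sqrt(np.where(np.isfinite(var), var, 0.0))

    z = stats.norm.ppf(1.0 - alpha / 2.0)
    lower = np.zeros_like(S)
    upper = np.ones_like(S)
    interior = (S > 0) & (S < 1) & np.isfinite(gw_term)
    with np.errstate(divide="ignore", invalid="ignore"):
        se_ll = np.sqrt(gw_term[interior]) / np.abs(np.log(S[interior]))
    lower[interior] = S[interior] ** np.exp(z * se_ll)
    upper[interior] = S[interior] ** np.exp(-z * se_ll)
    lower[S == 0] = 0.0
    upper[S == 0] = 0.0
    lower[S == 1] = 1.0
    upper[S == 1] = 1.0

    median = _first_crossing(times, S, 0.5)
    median_ci = (
        _first_crossing(times, lower, 0.5),
        _first_crossing(times, upper, 0.5),
    )
    return KMCurve(
        event_times=times, survival=S, greenwood_se=se,
        ci_lower=lower, ci_upper=upper,
        median=median, median_ci=median_ci,
        n=surv.n, n_events=surv.n_events,
    )


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


def logrank_test(surv, group) -> LogRankResult:
    """K-sample log-rank test.

    Sums observed-minus-expected event counts per group over the distinct
    event times, with the hypergeometric variance; the statistic is the
    quadratic form over the first K-1 groups and is chi-square with K-1
    degrees of freedom under the null of equal survival.
    """
    surv = as_survival_data(surv)
    g = np.asarray(group)
    if len(g) != surv.n:
        raise ValueError("group labels must match survival data length")
    labels, gidx = np.unique(g, return_inverse=True)
    K = len(labels)
    if K < 2:
        raise ValueError("log-rank test requires at least two groups")
    if surv.n_events < 1:
        raise ValueError("log-rank test requires at least one event")

    event_times = np.unique(surv.time[surv.event == 1])
    # per-group sorted times for fast at-risk counts
    times_by_group = [np.sort(surv.time[gidx == k]) for k in range(K)]
    OmE = np.zeros(K)
    V = np.zeros((K, K))
    for tj in event_times:
        nkj = np.array([len(tk) - np.searchsorted(tk, tj, side="left")
                        for tk in times_by_group], dtype=float)
        n = nkj.sum()
        at_event = (surv.time == tj) & (surv.event == 1)
        dkj = np.bincount(gidx[at_event], minlength=K).astype(float)
        dj = dkj.sum()
        frac = nkj / n
        OmE += dkj - dj * frac
        if n > 1:
            c = dj * (n - dj) / (n - 1.0)
            V += c * (np.diag(frac) - np.outer(frac, frac))
    Vr = V[: K - 1, : K - 1]
    u = OmE[: K - 1]
    try:
        stat = float(u @ np.linalg.solve(Vr, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(Vr) @ u)
    stat = max(stat, 0.0)
    df = K - 1
    p = float(stats.chi2.sf(stat, df)) if stat > 0 else 1.0
    return LogRankResult(chi_square=stat, df=df, p_value=p)


# ---------------------------------------------------------------------------
# restricted cubic splines
# ---------------------------------------------------------------------------

_RCS_QUANTILES = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
}


def default_rcs_knots(x, n_knots: int = 4) -> np.ndarray:
    """Knot placement at Harrell's recommended marginal quantiles."""
    x = np.asarray(x, dtype=float)
    if n_knots < 3:
        raise ValueError("restricted cubic splines need at least 3 knots")
    q = _RCS_QUANTILES.get(n_knots, tuple(np.linspace(0.05, 0.95, n_knots)))
    knots = np.quantile(x, q)
    if not np.all(np.diff(knots) > 0):
        raise ValueError("quantile knots are not strictly increasing; "
                         "marker has too many ties")
    return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Truncated-power restricted cubic spline basis.

    Returns ``(n, k-1)`` columns: the linear term followed by ``k-2``
    nonlinear terms constructed to be linear beyond the boundary knots,
    normalised by the squared boundary-knot span.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or len(t) < 3:
        raise ValueError("at least 3 knots required")
    if not np.all(np.diff(t) > 0):
        raise ValueError("knots must be strictly increasing")
    k = len(t)
    norm = (t[-1] - t[0]) ** 2

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    span = t[-1] - t[-2]
    for j in range(k - 2):
        term = (
            cube(x - t[j])
            - cube(x - t[-2]) * (t[-1] - t[j]) / span
            + cube(x - t[-1]) * (t[-2] - t[j]) / span
        )
        cols.append(term / norm)
    return np.column_stack(cols)


@dataclasses.dataclass
class RCSCurve:
    """Log relative-hazard curve on a spline basis, centred at ``center``."""

    grid: np.ndarray
    log_relative_hazard: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    lr_test_p: float
    knots: np.ndarray
    center: float
    coef: np.ndarray
    covariance: np.ndarray

    def evaluate(self, x) -> np.ndarray:
        """Centred curve value at arbitrary marker levels."""
        A = rcs_basis(np.atleast_1d(x), self.knots) - rcs_basis(
            np.array([self.center]), self.knots
        )
        return A @ self.coef


def rcs_loghazard(ri, surv, n_knots: int = 4, knots=None,
                  grid_size: int = 101, alpha: float = 0.05,
                  ties: str = "efron") -> RCSCurve:
    """Cox fit of survival on the restricted cubic spline basis of a marker.

    The curve is the fitted log relative hazard over a grid of marker
    values, centred to 0 at the cohort median; pointwise bands come from
    the delta method and the association p-value from the likelihood-ratio
    test on the basis dimension.
    """
    ri = np.asarray(ri, dtype=float)
    if not np.isfinite(ri).all():
        raise ValueError("marker values must be finite")
    surv = as_survival_data(surv)
    if knots is None:
        knots = default_rcs_knots(ri, n_knots)
    knots = np.asarray(knots, dtype=float)
    B = rcs_basis(ri, knots)
    fit = CoxPH(ties=ties).fit(B, surv)
    center = float(np.median(ri))
    grid = np.unique(np.concatenate(
        [np.linspace(ri.min(), ri.max(), grid_size), [center]]
    ))
    A = rcs_basis(grid, knots) - rcs_basis(np.array([center]), knots)
    curve = A @ fit.coef_
    var = np.einsum("ij,jk,ik->i", A, fit.covariance_, A)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(np.maximum(var, 0.0))
    lr_stat = max(2.0 * (fit.loglik_ - fit.loglik_null_), 0.0)
    lr_p = float(stats.chi2.sf(lr_stat, B.shape[1]))
    return RCSCurve(
        grid=grid, log_relative_hazard=curve,
        ci_lower=curve - half, ci_upper=curve + half,
        lr_test_p=lr_p, knots=knots, center=center,
        coef=fit.coef_, covariance=fit.covariance_,
    )


# ---------------------------------------------------------------------------
# time-dependent ROC
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TdROC:
    """Cumulative-case / dynamic-control ROC at a fixed horizon (months)."""

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def _km_at_time(time: np.ndarray, event: np.ndarray, t: float) -> float:
    """Product-limit S(t) for a subgroup (1.0 for an empty subgroup)."""
    if len(time) == 0:
        return 1.0
    mask = (event == 1) & (time <= t)
    if not mask.any():
        return 1.0
    ets = np.unique(time[mask])
    sorted_t = np.sort(time)
    n_at_risk = len(time) - np.searchsorted(sorted_t, ets, side="left")
    sorted_et = np.sort(time[event == 1])
    d = (np.searchsorted(sorted_et, ets, side="right")
         - np.searchsorted(sorted_et, ets, side="left"))
    return float(np.prod(1.0 - d / n_at_risk))


def td_roc(marker, surv, horizon: float, max_thresholds: int = 1000) -> TdROC:
    """Time-dependent ROC with cases = events by the horizon and controls =
    event-free beyond it, estimated by Kaplan-Meier conditioning on marker
    exceedance (Bayes inversion) so censored subjects contribute through the
    subgroup survival curves.  AUC by the trapezoidal rule.
    """
    marker = np.asarray(marker, dtype=float)
    if not np.isfinite(marker).all():
        raise ValueError("marker values must be finite")
    surv = as_survival_data(surv)
    if len(marker) != surv.n:
        raise ValueError("marker and survival data have different lengths")
    if not (surv.time.min() <= horizon <= surv.time.max()):
        raise ValueError("horizon must lie within the observed time range")
    if not ((surv.event == 1) & (surv.time <= horizon)).any():
        raise UndefinedROCError("no events observed by the horizon")
    S_t = _km_at_time(surv.time, surv.event, horizon)
    if S_t <= 0.0:
        raise UndefinedROCError("no survivors past the horizon; controls undefined")

    thresholds = np.unique(marker)
    if len(thresholds) > max_thresholds:
        thresholds = np.unique(np.quantile(
            marker, np.linspace(0.0, 1.0, max_thresholds)
        ))
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, c in enumerate(thresholds):
        high = marker > c
        p1 = high.mean()
        S_high = _km_at_time(surv.time[high], surv.event[high], horizon)
        S_low = _km_at_time(surv.time[~high], surv.event[~high], horizon)
        sens[i] = (1.0 - S_high) * p1 / (1.0 - S_t)
        spec[i] = S_low * (1.0 - p1) / S_t
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # integrate along the threshold-ordered path from (1,1) down to (0,0);
    # thresholds ascend, so the false-positive rate descends along the path
    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(-np.trapezoid(tpr, fpr))
    return TdROC(horizon=float(horizon), thresholds=thresholds,
                 sensitivity=sens, specificity=spec, auc=auc)
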