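"""Independent oracles used by the tests.

These are deliberately naive implementations (grid search, direct
summation) kept separate from the package so they cannot share bugs with
the code under test.
"""

import numpy as np


def efron_partial_loglik(beta, time, event, x):
    """Hand-written single-covariate Cox partial log-likelihood (Efron ties)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    theta = np.exp(beta * x)
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = time >= t
        d = int(D.sum())
        s0 = theta[R].sum()
        sd = theta[D].sum()
        ll += beta * x[D].sum()
        for l in range(d):
            ll -= np.log(s0 - (l / d) * sd)
    return ll


def grid_cox_mle(time, event, x, lo=-5.0, hi=5.0, step=1e-4):
    """Brute-force maximiser of the partial likelihood over a grid.

    Vectorised over the grid but summing the same per-event-time Efron
    terms as :func:`efron_partial_loglik`.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    grid = np.arange(lo, hi + step / 2, step)
    theta = np.exp(np.outer(grid, x))  # (G, n)
    lls = np.zeros(len(grid))
    for t in np.unique(time[event == 1]):
        D = (time == t) & (event == 1)
        R = time >= t
        d = int(D.sum())
        s0 = theta[:, R].sum(axis=1)
        sd = theta[:, D].sum(axis=1)
        lls += grid * x[D].sum()
        for l in range(d):
            lls -= np.log(s0 - (l / d) * sd)
    return float(grid[np.argmax(lls)])


def hand_logrank_2group(time, event, group):
    """Direct per-event-time 2x2 hypergeometric O-E / V summation."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    o_minus_e = 0.0
    v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n - d) / (n - 1) * (n1 / n) * (1 - n1 / n)
    return o_minus_e**2 / v


def hand_km(time, event):
    """Direct product-limit computation returning (times, survival)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    out_t, out_s = [], []
    s = 1.0
    for t in np.unique(time[event == 1]):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)
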