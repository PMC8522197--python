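"""Independent brute-force oracles used to check the implementation.

Everything here is written from first principles (explicit loops over
definitions) and stays independent of the library code paths it checks.
"""
from __future__ import annotations

import math

import numpy as np


def breslow_loglik_slow(beta: float, x, time, event) -> float:
    """Breslow partial log-likelihood of a scalar coefficient, by definition."""
    x = list(map(float, x))
    n = len(x)
    ll = 0.0
    for i in range(n):
        if not event[i]:
            continue
        risk = [j for j in range(n) if time[j] >= time[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


def breslow_beta_grid(x, time, event, lo=-10.0, hi=10.0) -> float:
    """Maximise the Breslow partial likelihood by iteratively refined grid search."""
    for _ in range(8):
        grid = np.linspace(lo, hi, 201)
        lls = [breslow_loglik_slow(b, x, time, event) for b in grid]
        k = int(np.argmax(lls))
        lo, hi = grid[max(0, k - 1)], grid[min(len(grid) - 1, k + 1)]
    return float((lo + hi) / 2)


def logrank_chi2_oracle(time_a, event_a, time_b, event_b) -> float:
    """Two-group log-rank chi-square by summing O-E and hypergeometric variance."""
    times = sorted(set([t for t, e in zip(time_a, event_a) if e]
                       + [t for t, e in zip(time_b, event_b) if e]))
    O_minus_E = 0.0
    V = 0.0
    for t in times:
        n_a = sum(1 for ta in time_a if ta >= t)
        n_b = sum(1 for tb in time_b if tb >= t)
        d_a = sum(1 for ta, ea in zip(time_a, event_a) if ea and ta == t)
        d_b = sum(1 for tb, eb in zip(time_b, event_b) if eb and tb == t)
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        v = d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
        O_minus_E += d_a - e_a
        V += v
    return O_minus_E**2 / V if V > 0 else 0.0


def bh_oracle(pvals) -> list[float]:
    """Benjamini-Hochberg step-up by definition: fdr_i = min_{j>=i} p_(j)*m/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def fisher_2x2_oracle(a, b, c, d) -> float:
    """Two-sided Fisher exact p by conditional hypergeometric enumeration."""
    def comb(n, k):
        return math.comb(n, k)

    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c) / denom
    p = 0.0
    for aa in range(max(0, c1 - r2), min(r1, c1) + 1):
        cc = c1 - aa
        pk = comb(r1, aa) * comb(r2, cc) / denom
        if pk <= p_obs * (1 + 1e-9):
            p += pk
    return p


def aic_cutoff_oracle(scores, time, event, min_group_frac=0.1) -> float:
    """Exhaustive min-AIC midpoint search using the grid-search Breslow fit."""
    s = np.asarray(scores, dtype=float)
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    floor = max(1, int(np.ceil(min_group_frac * len(s))))
    best, best_aic = None, np.inf
    for c in mids:
        ind = (s > c).astype(float)
        if ind.sum() < floor or (1 - ind).sum() < floor:
            continue
        beta = breslow_beta_grid(ind, time, event)
        aic = 2.0 - 2.0 * breslow_loglik_slow(beta, ind, time, event)
        if aic < best_aic - 1e-12:
            best_aic, best = aic, float(c)
    return best


def mann_whitney_auc(case_scores, control_scores) -> float:
    """Concordance of (case, control) pairs; ties count one half."""
    num = 0.0
    for sc in case_scores:
        for st in control_scores:
            num += 1.0 if sc > st else (0.5 if sc == st else 0.0)
    return num / (len(case_scores) * len(control_scores))
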