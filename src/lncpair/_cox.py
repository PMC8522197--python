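"""Breslow partial-likelihood machinery for binary covariates.

The pair screen fits thousands of single-covariate Cox models on 0/1 pair
indicators. For a binary covariate the Breslow partial likelihood depends on
the data only through, at each distinct event time, the number of events,
the number of events with x = 1, and the at-risk counts split by x — so the
Newton iteration vectorises across all pairs at once.

    l(b)  = sum_k [ b*dx_k - d_k * log(n0_k + n1_k * exp(b)) ]
    U(b)  = sum_k [ dx_k - d_k * n1_k e^b / (n0_k + n1_k e^b) ]
    I(b)  = sum_k   d_k * n0_k n1_k e^b / (n0_k + n1_k e^b)^2

where, at the k-th distinct event time, d_k = events, dx_k = events with
x = 1, and n1_k / n0_k = at-risk subjects with x = 1 / x = 0.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: |beta| beyond which the likelihood is treated as monotone (perfect separation).
BETA_CAP = 15.0


@dataclass
class BinaryCoxFit:
    """Per-covariate results of the vectorised binary-covariate Cox fit."""

    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    loglik: np.ndarray
    loglik_null: float
    separated: np.ndarray  # monotone-likelihood flag; beta capped at +/-BETA_CAP


def _event_time_counts(time: np.ndarray, event: np.ndarray, X: np.ndarray):
    """Risk-set and event counts at each distinct event time.

    Returns (d, dx, n1, n_at_risk): d (k,), dx and n1 (p, k), n_at_risk (k,).
    """
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order].astype(bool)
    Xs = X[:, order]  # (p, n)
    n = len(t_sorted)

    event_times = np.unique(t_sorted[e_sorted])  # ascending
    k = len(event_times)
    # index of first subject with time >= t_k  -> at-risk suffix start
    start = np.searchsorted(t_sorted, event_times, side="left")
    # suffix sums of x over sorted subjects
    suffix = np.concatenate(
        [np.cumsum(Xs[:, ::-1], axis=1)[:, ::-1], np.zeros((X.shape[0], 1))], axis=1
    )
    n1 = suffix[:, start]  # (p, k)
    n_at_risk = (n - start).astype(float)  # (k,)

    d = np.zeros(k)
    dx = np.zeros((X.shape[0], k))
    ev_idx = np.flatnonzero(e_sorted)
    pos = np.searchsorted(event_times, t_sorted[ev_idx])
    np.add.at(d, pos, 1.0)
    for p_, i_ in zip(pos, ev_idx):
        dx[:, p_] += Xs[:, i_]
    return d, dx, n1, n_at_risk


def fit_binary_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                   max_iter: int = 60, tol: float = 1e-10) -> BinaryCoxFit:
    """Fit a single-covariate Breslow Cox model for every row of a 0/1 matrix.

    Parameters
    ----------
    X : (p, n) array of 0/1 indicators, one covariate per row.
    time, event : (n,) survival time and 0/1 event flag.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if not np.isin(X, [0.0, 1.0]).all():
        raise ValueError("fit_binary_cox expects 0/1 covariates")
    constant = X.std(axis=1) == 0
    if constant.any():
        i = int(np.flatnonzero(constant)[0])
        raise ValueError(f"constant indicator column at row {i}; cannot fit Cox model")

    d, dx, n1, n_risk = _event_time_counts(time, event, X)
    n0 = n_risk[None, :] - n1
    dx_tot = dx.sum(axis=1)

    beta = np.zeros(X.shape[0])
    for _ in range(max_iter):
        eb = np.exp(beta)[:, None]
        denom = n0 + n1 * eb
        frac = n1 * eb / denom
        U = dx_tot - (d[None, :] * frac).sum(axis=1)
        info = (d[None, :] * n0 * n1 * eb / denom**2).sum(axis=1)
        step = U / np.maximum(info, 1e-12)
        step = np.clip(step, -2.0, 2.0)  # damp early oversized steps
        beta = np.clip(beta + step, -BETA_CAP, BETA_CAP)
        if np.max(np.abs(step)) < tol:
            break

    separated = np.abs(beta) >= BETA_CAP
    eb = np.exp(beta)[:, None]
    denom = n0 + n1 * eb
    info = (d[None, :] * n0 * n1 * eb / denom**2).sum(axis=1)
    se = 1.0 / np.sqrt(np.maximum(info, 1e-300))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    loglik = beta * dx_tot - (d[None, :] * np.log(denom)).sum(axis=1)
    loglik_null = float(-(d * np.log(n_risk)).sum())
    return BinaryCoxFit(beta=beta, se=se, p=p, loglik=loglik,
                        loglik_null=loglik_null, separated=separated)


def breslow_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> float:
    """Breslow partial log-likelihood of a coefficient vector on a dataset.

    ``X`` is (n, p); used to score held-out folds during lasso penalty CV.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    eta = X @ beta
    order = np.argsort(time, kind="stable")
    t_sorted = np.asarray(time, dtype=float)[order]
    e_sorted = np.asarray(event)[order].astype(bool)
    eta_sorted = eta[order]
    if not e_sorted.any():
        return 0.0
    event_times = np.unique(t_sorted[e_sorted])
    start = np.searchsorted(t_sorted, event_times, side="left")
    # suffix log-sum-exp of eta
    m = eta_sorted.max()
    suffix = np.concatenate([np.cumsum(np.exp(eta_sorted - m)[::-1])[::-1], [0.0]])
    log_den = m + np.log(suffix[start])
    pos = np.searchsorted(event_times, t_sorted[e_sorted])
    d = np.zeros(len(event_times))
    eta_sum = np.zeros(len(event_times))
    np.add.at(d, pos, 1.0)
    np.add.at(eta_sum, pos, eta_sorted[e_sorted])
    return float((eta_sum - d * log_den).sum())
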