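"""Compact vectorized Newton solver for the Cox partial likelihood
(Breslow ties).

The resampling loops of the risk-prediction module (bootstrap confidence
intervals, permutation nulls) refit small Cox models tens of thousands of
times; this kernel keeps those loops fast.  It is deliberately minimal:
point estimates and the observed-information covariance only.  User-facing
adjusted fits go through lifelines.
"""

from __future__ import annotations

import numpy as np


def _risk_sums(times: np.ndarray):
    """Sort order plus, for each sorted position, the index of the first
    member of its tie group (so reverse cumulative sums taken at that index
    cover the full Breslow risk set {j: t_j >= t_i})."""
    order = np.argsort(times, kind="stable")
    t_s = times[order]
    first = np.searchsorted(t_s, t_s, side="left")
    return order, t_s, first


def cox_partial_loglik(times, events, lp) -> float:
    """Breslow partial log-likelihood of a fixed linear predictor."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    lp = np.asarray(lp, dtype=float)
    lp = lp - lp.max()
    order, _, first = _risk_sums(times)
    e_s = events[order]
    lp_s = lp[order]
    w = np.exp(lp_s)
    rev = np.cumsum(w[::-1])[::-1]
    ev = e_s == 1
    return float(lp_s[ev].sum() - np.log(rev[first[ev]]).sum())


def cox_partial_loglik_multi(times, events, lp_matrix) -> np.ndarray:
    """Breslow partial log-likelihood for each column of an (n, L) matrix of
    linear predictors (one sort shared across all L)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events)
    lp = np.asarray(lp_matrix, dtype=float)
    lp = lp - lp.max(axis=0, keepdims=True)
    order, _, first = _risk_sums(times)
    e_s = events[order]
    lp_s = lp[order]
    w = np.exp(lp_s)
    rev = np.cumsum(w[::-1], axis=0)[::-1]
    ev = e_s == 1
    return lp_s[ev].sum(axis=0) - np.log(rev[first[ev]]).sum(axis=0)


def _loglik_grad_hess(times, events, x, beta, want_derivs=True):
    # underflow of exp(eta - max) at extreme beta gives 0/0 terms here;
    # the resulting non-finite log-likelihood is handled by the caller's
    # step-halving and convergence guard, so silence the warnings
    with np.errstate(divide="ignore", invalid="ignore"):
        return _loglik_grad_hess_raw(times, events, x, beta, want_derivs)


def _loglik_grad_hess_raw(times, events, x, beta, want_derivs=True):
    n, p = x.shape
    eta = x @ beta
    shift = eta.max()
    w_all = np.exp(eta - shift)
    order, _, first = _risk_sums(times)
    e_s = events[order]
    x_s = x[order]
    eta_s = eta[order] - shift
    w = w_all[order]
    ev = e_s == 1
    s0 = np.cumsum(w[::-1])[::-1][first[ev]]
    ll = float(eta_s[ev].sum() - np.log(s0).sum())
    if not want_derivs:
        return ll, None, None
    wx = w[:, None] * x_s
    s1 = np.cumsum(wx[::-1], axis=0)[::-1][first[ev]]
    wxx = wx[:, :, None] * x_s[:, None, :]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1][first[ev]]
    mu = s1 / s0[:, None]
    grad = x_s[ev].sum(axis=0) - mu.sum(axis=0)
    hess = (s2 / s0[:, None, None]).sum(axis=0) - mu.T @ mu
    return ll, grad, hess


def fit_cox(times, events, x, max_iter: int = 60, tol: float = 1e-9,
            ridge: float = 1e-9):
    """Newton-Raphson fit; returns (beta, cov, loglik, converged).

    Monotone-likelihood configurations (a covariate perfectly ordering the
    events) drive coefficients to infinity; the fit then stops with
    ``converged=False`` and an unreliable covariance.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    beta = np.zeros(p)
    if p == 0:
        ll = cox_partial_loglik(times, events, np.zeros(n))
        return beta, np.zeros((0, 0)), ll, True
    ll_old = -np.inf
    converged = False
    ll_new = -np.inf
    for _ in range(max_iter):
        ll, grad, hess = _loglik_grad_hess(times, events, x, beta)
        h = hess + ridge * np.eye(p)
        try:
            step = np.linalg.solve(h, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(h, grad, rcond=None)[0]
        # step halving keeps the likelihood monotone
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, _, _ = _loglik_grad_hess(times, events, x, cand,
                                             want_derivs=False)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if abs(ll_new - ll_old) < tol * (abs(ll_old) + 1):
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    ll_final, _, hess = _loglik_grad_hess(times, events, x, beta)
    try:
        cov = np.linalg.inv(hess + ridge * np.eye(p))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.inf)
    if np.linalg.norm(beta) > 50:
        converged = False
    return beta, cov, ll_final, converged
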