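"""Vectorized Newton-Raphson solver for the Cox partial likelihood.

The univariate screen and the forward-selection loop need thousands of small
Cox fits per run, so this solver keeps the per-fit overhead minimal: the
Efron-corrected negative log partial likelihood, its gradient and Hessian are
assembled with reverse cumulative sums and segment sums, with an optional L2
(ridge) penalty for stability near collinearity. Coefficients agree with
standard Cox software (see tests) on data with and without tied event times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CoxFitResult:
    beta: np.ndarray
    converged: bool
    n_iter: int
    loglik: float


def _efron_quantities(beta, x, t_sorted_info):
    """Negative log partial likelihood, gradient and Hessian (Efron ties)."""
    xs, es, ev_rows, grp_start, l_frac = t_sorted_info
    n, p = xs.shape
    eta = xs @ beta
    eta = np.clip(eta, -200, 200)
    w = np.exp(eta)
    wx = w[:, None] * xs
    # reverse cumulative sums: S*(i) = sum over the risk set {j : t_j >= t_i}
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    wxx = wx[:, :, None] * xs[:, None, :]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    # per-event tie-group sums (events are contiguous within a time group)
    w_ev, wx_ev, wxx_ev = w[ev_rows], wx[ev_rows], wxx[ev_rows]
    seg = np.concatenate([[True], grp_start[1:] != grp_start[:-1]])
    starts = np.flatnonzero(seg)
    wD = np.add.reduceat(w_ev, starts)
    sD1 = np.add.reduceat(wx_ev, starts, axis=0)
    sD2 = np.add.reduceat(wxx_ev, starts, axis=0)
    grp_idx = np.cumsum(seg) - 1

    denom = S0[grp_start] - l_frac * wD[grp_idx]
    num1 = S1[grp_start] - l_frac[:, None] * sD1[grp_idx]
    num2 = S2[grp_start] - l_frac[:, None, None] * sD2[grp_idx]

    nll = -(eta[ev_rows].sum() - np.log(denom).sum())
    mu = num1 / denom[:, None]
    grad = -(xs[ev_rows].sum(axis=0) - mu.sum(axis=0))
    hess = (num2 / denom[:, None, None]).sum(axis=0) - np.einsum("ij,ik->jk", mu, mu)
    return nll, grad, hess


def _prepare(x: np.ndarray, time: np.ndarray, event: np.ndarray):
    order = np.argsort(time, kind="stable")
    xs = np.ascontiguousarray(x[order], dtype=float)
    ts = time[order]
    es = event[order].astype(bool)
    ev_rows = np.flatnonzero(es)
    t_ev = ts[ev_rows]
    # first row of each event's risk set (ties share a risk set)
    grp_start = np.searchsorted(ts, t_ev, side="left")
    # Efron fraction l/d within each tie group of events
    uniq, counts = np.unique(grp_start, return_counts=True)
    l_within = np.concatenate([np.arange(c) for c in counts])
    d = np.repeat(counts, counts)
    l_frac = l_within / d
    return xs, es, ev_rows, grp_start, l_frac


def cox_newton(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    l2: float = 1e-6,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> CoxFitResult:
    """Fit log-partial-hazard coefficients beta for risk = x @ beta.

    Returns a non-converged result (rather than raising) for degenerate
    inputs such as zero-variance covariates, so scanning loops can treat the
    feature as uninformative.
    """
    x = np.asarray(x, float)
    if x.ndim == 1:
        x = x[:, None]
    time = np.asarray(time, float)
    event = np.asarray(event, float)
    n, p = x.shape
    if event.sum() == 0:
        return CoxFitResult(np.zeros(p), False, 0, -np.inf)
    info = _prepare(x, time, event)
    beta = np.zeros(p)
    nll, grad, hess = _efron_quantities(beta, x, info)
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(hess + l2 * np.eye(p), grad + l2 * beta)
        except np.linalg.LinAlgError:
            return CoxFitResult(beta, False, it, -nll)
        if not np.all(np.isfinite(step)):
            return CoxFitResult(beta, False, it, -nll)
        # backtracking line search on the penalized objective
        f0 = nll + 0.5 * l2 * beta @ beta
        scale = 1.0
        for _ in range(30):
            cand = beta - scale * step
            nll_c, grad_c, hess_c = _efron_quantities(cand, x, info)
            if nll_c + 0.5 * l2 * cand @ cand <= f0 + 1e-12:
                break
            scale *= 0.5
        else:
            return CoxFitResult(beta, False, it, -nll)
        delta = np.max(np.abs(cand - beta))
        beta, nll, grad, hess = cand, nll_c, grad_c, hess_c
        if delta < tol:
            return CoxFitResult(beta, True, it, -nll)
    return CoxFitResult(beta, False, it, -nll)
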