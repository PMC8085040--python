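"""Breslow partial-likelihood primitives and a dense Newton-Raphson fitter.

These are shared by the penalized spline model, the bootstrap ROC stage and
the small-lambda oracle checks of the elastic-net path.  Everything works on
pre-sorted arrays; ties are handled with the Breslow approximation.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "breslow_loglik",
    "breslow_grad_hess",
    "newton_cox",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    pass


def _sorted(time, event, X=None):
    order = np.argsort(time, kind="stable")
    if X is None:
        return time[order], event[order], order
    return time[order], event[order], X[order], order


def _tie_groups(t_sorted):
    """Start indices of tie groups in an ascending-sorted time vector."""
    n = t_sorted.size
    starts = np.r_[0, 1 + np.nonzero(np.diff(t_sorted) != 0)[0]]
    ends = np.r_[starts[1:], n]
    return starts, ends

def _group_arrays(t_sorted, e_sorted):
    """Tie-group starts with per-group event counts (ascending times)."""
    starts, ends = _tie_groups(t_sorted)
    d = np.add.reduceat(e_sorted, starts)
    keep = d > 0
    return starts[keep], d[keep].astype(float)


def breslow_loglik(eta, time, event):
    """Breslow log partial likelihood for linear predictor ``eta``."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    eta = np.asarray(eta, float)
    order = np.argsort(time, kind="stable")
    t, e, h = time[order], event[order], eta[order]
    r = np.exp(np.clip(h, -500, 500))
    suffix = np.cumsum(r[::-1])[::-1]
    starts, d = _group_arrays(t, e)
    return float(h[e == 1].sum() - (d * np.log(suffix[starts])).sum())


def breslow_grad_hess(eta, time, event, X):
    """Gradient and (negative) Hessian of the Breslow log PL wrt beta.

    Returns ``(loglik, grad, info)`` with ``info`` the observed information
    matrix (positive semi-definite).
    """
    t, e, Xs, order = _sorted(np.asarray(time, float), np.asarray(event, int),
                              np.asarray(X, float))
    h = np.asarray(eta, float)[order]
    n, p = Xs.shape
    r = np.exp(np.clip(h, -500, 500))
    rx = r[:, None] * Xs
    S0 = np.cumsum(r[::-1])[::-1]
    S1 = np.cumsum(rx[::-1], axis=0)[::-1]
    starts, d = _group_arrays(t, e)
    ev = e == 1
    ll = float(h[ev].sum() - (d * np.log(S0[starts])).sum())
    means = S1[starts] / S0[starts, None]  # (G, p)
    grad = Xs[ev].sum(axis=0) - d @ means
    # info = sum_g d_g * (S2_g/S0_g - mean_g mean_g')
    # S2 suffix sums computed via reversed cumulative of r*x x' without
    # materializing (n,p,p): accumulate per-group with matmuls on slices.
    weights = np.zeros(n)
    # weight for subject i: sum over groups g with start_g <= i of d_g/S0_g
    wg = d / S0[starts]
    cum = np.zeros(len(starts))
    np.cumsum(wg, out=cum)
    idx = np.searchsorted(starts, np.arange(n), side="right") - 1
    valid = idx >= 0
    weights[valid] = cum[idx[valid]]
    # sum_g d_g S2_g / S0_g = sum_i (sum_{g: start_g <= i} d_g/S0_g) r_i x_i x_i'
    info = (Xs * (weights * r)[:, None]).T @ Xs
    info -= (means * d[:, None]).T @ means
    return ll, grad, info


def newton_cox(X, time, event, penalty=None, beta0=None, tol=1e-9, max_iter=60):
    """Penalized Newton-Raphson Cox fit (Breslow ties).

    Maximizes ``loglik(beta) - 0.5 * beta' P beta`` where ``P`` is an optional
    penalty matrix (``None`` means unpenalized).  Returns
    ``(beta, loglik, info)`` with ``loglik`` the *unpenalized* log partial
    likelihood at the solution and ``info`` the unpenalized observed
    information.  Raises :class:`ConvergenceError` on monotone likelihood.
    """
    X = np.asarray(X, float)
    n, p = X.shape
    if penalty is None:
        penalty = np.zeros((p, p))
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    eta = X @ beta
    ll, grad, info = breslow_grad_hess(eta, time, event, X)
    pen_ll = ll - 0.5 * beta @ penalty @ beta
    for _ in range(max_iter):
        g = grad - penalty @ beta
        H = info + penalty
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            raise ConvergenceError("non-finite Newton step")
        # step halving
        scale = 1.0
        for _half in range(40):
            cand = beta + scale * step
            ll_c = breslow_loglik(X @ cand, time, event)
            pen_c = ll_c - 0.5 * cand @ penalty @ cand
            if pen_c >= pen_ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        delta = scale * np.max(np.abs(step))
        beta = cand
        eta = X @ beta
        ll, grad, info = breslow_grad_hess(eta, time, event, X)
        pen_ll = ll - 0.5 * beta @ penalty @ beta
        if np.max(np.abs(beta)) > 200:
            raise ConvergenceError("diverging coefficients (monotone likelihood?)")
        if delta < tol:
            return beta, ll, info
    raise ConvergenceError("Newton-Raphson did not converge")
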