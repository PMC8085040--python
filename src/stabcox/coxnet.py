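"""Elastic-net penalized Cox regression along a lambda path with CV selection.

The fitted objective is

    -(1/n) * Breslow log partial likelihood
        + lambda * sum_j m_j * (alpha*|beta_j| + (1-alpha)/2 * beta_j^2)

with mixing parameter ``alpha`` in (0, 1], penalty strength ``lambda`` and
optional per-feature multipliers ``m_j`` (all 1 by default).  ``lambda_max``
is the smallest lambda with an all-zero solution; the path is log-spaced down
to ``lambda_max * lambda_min_ratio`` and solved with warm starts.

Model selection follows a two-level cross-validation rule: an equally spaced
alpha grid on [0, 1]; for each alpha the lambda minimizing the cross-validated
partial-likelihood deviance (Verweij-van-Houwelingen form); then the
error-minimizing alpha restricted to alpha > 0 (alpha = 0 is ridge and never
selects variables).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _ennet
from .cohort import SurvivalResponse

logger = logging.getLogger(__name__)

__all__ = [
    "ElasticNetConfig",
    "ElasticNetPath",
    "CVSelection",
    "coxnet_fit_path",
    "coxnet_cv_select",
    "kkt_violation",
]


@dataclass
class ElasticNetConfig:
    """Controls for the path solver and the (alpha, lambda) cross-validation."""

    n_alphas: int = 15
    folds: int = 20
    path_length: int = 100
    lambda_min_ratio: float = 0.05
    tol: float = 1e-7
    max_iter: int = 100
    tie_method: str = "breslow"
    standardize: bool = True
    max_active: int | None = None  # dfmax-style early path termination

    def __post_init__(self) -> None:
        if self.n_alphas < 2:
            raise ValueError("n_alphas must be >= 2")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.tie_method != "breslow":
            raise ValueError("only Breslow ties are supported in the penalized fitter")

    @property
    def alpha_grid(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_alphas)


@dataclass
class ElasticNetPath:
    """Coefficient path: p x L matrix over a strictly decreasing lambda grid.

    Coefficients are reported on the original (unstandardized) column scale.
    """

    alpha: float
    lambdas: np.ndarray
    coefficients: np.ndarray
    penalty_multipliers: np.ndarray
    feature_names: list[str] | None = None
    n_computed: int | None = None  # grid points actually solved (dfmax stop)

    def active_sets(self) -> list[np.ndarray]:
        return [np.nonzero(self.coefficients[:, l])[0] for l in range(self.lambdas.size)]

    def to_long_frame(self):
        import pandas as pd

        p, L = self.coefficients.shape
        names = self.feature_names or [f"x{j}" for j in range(p)]
        recs = [
            {"alpha": self.alpha, "lambda": self.lambdas[l], "feature": names[j],
             "coefficient": self.coefficients[j, l]}
            for l in range(L) for j in range(p)
        ]
        return pd.DataFrame(recs)


@dataclass
class CVSelection:
    cv_error: dict
    best_alpha: float
    best_lambda: float
    lambda_per_alpha: dict = field(default_factory=dict)


def _design_arrays(X):
    """Accept an EncodedDesign, DataFrame or ndarray."""
    names = None
    if hasattr(X, "frame"):
        names = list(X.frame.columns)
        mat = X.frame.to_numpy(dtype=float)
    elif hasattr(X, "to_numpy"):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
    if np.isnan(mat).any():
        raise ValueError("design matrix contains missing entries")
    return mat, names


def _standardize(mat):
    mean = mat.mean(axis=0)
    sd = mat.std(axis=0)  # 1/n variance, glmnet convention
    ok = sd > 0
    Xs = np.zeros_like(mat)
    Xs[:, ok] = (mat[:, ok] - mean[ok]) / sd[ok]
    return Xs, sd, ok


def lambda_max_value(Xs, time, event, alpha, m, n):
    """Smallest lambda at which the all-zero solution satisfies the KKT
    conditions: max_j |score_j(0)| / (alpha * m_j)."""
    order = np.argsort(time, kind="stable")
    g0, _w, _ll = _ennet.breslow_gw(np.zeros(n), time[order], event[order])
    score = np.abs(Xs[order].T @ g0) / n
    with np.errstate(divide="ignore"):
        vals = score / (alpha * m)
    vals[~np.isfinite(vals)] = 0.0
    # tiny upward nudge so the all-zero solution is strictly inside the
    # KKT region at the first grid point
    return float(vals.max()) * (1.0 + 1e-6)


def coxnet_fit_path(
    X,
    y: SurvivalResponse,
    alpha: float,
    config: ElasticNetConfig | None = None,
    penalty_multipliers=None,
    lambdas=None,
) -> ElasticNetPath:
    """Fit the elastic-net Cox coefficient path.

    If ``lambdas`` is omitted the grid is auto-generated (requires
    ``alpha > 0``).  ``penalty_multipliers`` are the per-feature m_j; scaling
    every m_j by c while dividing lambda by c leaves the solution unchanged.
    """
    config = config or ElasticNetConfig()
    mat, names = _design_arrays(X)
    n, p = mat.shape
    if y.n != n:
        raise ValueError("design and response lengths differ")
    if y.n_events == 0:
        raise ValueError("cannot fit with zero events")
    m = np.ones(p) if penalty_multipliers is None else np.asarray(penalty_multipliers, float).copy()
    if m.shape != (p,) or (m <= 0).any():
        raise ValueError("penalty multipliers must be positive, one per feature")

    if config.standardize:
        Xs, sd, ok = _standardize(mat)
    else:
        Xs, sd, ok = mat, np.ones(p), mat.std(axis=0) > 0

    if lambdas is None:
        if not 0 < alpha <= 1:
            raise ValueError("alpha must be in (0, 1] for automatic lambda-path generation")
        lam_max = lambda_max_value(Xs, y.time, y.event, alpha, m, n)
        lambdas = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.path_length)
    else:
        lambdas = np.asarray(lambdas, float)
        if np.any(np.diff(lambdas) >= 0):
            raise ValueError("lambda grid must be strictly decreasing")

    order = np.argsort(y.time, kind="stable")
    coefs_std, n_computed = _ennet.cd_path(
        np.asfortranarray(Xs[order]),
        y.time[order],
        y.event[order].astype(np.int64),
        np.asarray(lambdas, float),
        float(alpha),
        m,
        config.tol,
        config.max_iter,
        1000,
        0 if config.max_active is None else int(config.max_active),
    )
    coefs = coefs_std.copy()
    if config.standardize:
        coefs[ok] = coefs_std[ok] / sd[ok, None]
        coefs[~ok] = 0.0
    return ElasticNetPath(alpha, np.asarray(lambdas, float), coefs, m, names,
                          int(n_computed))


def kkt_violation(path: ElasticNetPath, X, y: SurvivalResponse, config=None, index=None):
    """Maximum KKT-condition violation along the path (diagnostic).

    For active features the subgradient condition is an equality
    ``score_j - lam*(1-alpha)*m_j*b_j = lam*alpha*m_j*sign(b_j)``; for
    inactive features ``|score_j| <= lam*alpha*m_j``.  Returns the largest
    violation over the requested path points (all by default).
    """
    config = config or ElasticNetConfig()
    mat, _ = _design_arrays(X)
    n, p = mat.shape
    if config.standardize:
        Xs, sd, ok = _standardize(mat)
    else:
        Xs, sd, ok = mat, np.ones(p), mat.std(axis=0) > 0
    order = np.argsort(y.time, kind="stable")
    Xo = Xs[order]
    worst = 0.0
    idxs = range(path.lambdas.size) if index is None else [index]
    for l in idxs:
        beta_std = path.coefficients[:, l] * np.where(ok, sd, 1.0)
        eta = Xo @ beta_std
        g, _w, _ll = _ennet.breslow_gw(eta, y.time[order], y.event[order])
        score = Xo.T @ g / n
        lam = path.lambdas[l]
        m = path.penalty_multipliers
        for j in range(p):
            if not ok[j]:
                continue
            if beta_std[j] != 0.0:
                viol = abs(score[j] - lam * (1 - path.alpha) * m[j] * beta_std[j]
                           - lam * path.alpha * m[j] * np.sign(beta_std[j]))
            else:
                viol = max(0.0, abs(score[j]) - lam * path.alpha * m[j])
            worst = max(worst, viol)
    return worst


def _fold_assignment(n, events, folds, rng, max_redraw=1000):
    """Uniformly random fold labels; redrawn until every fold has an event.

    With fewer events than requested folds that condition is unattainable, so
    the fold count is capped at the event count (warned)."""
    n_events = int(events.sum())
    if n_events == 0:
        raise ValueError("cannot cross-validate with zero events")
    folds_eff = min(folds, max(2, n_events))
    if folds_eff < folds:
        warnings.warn(f"only {n_events} events: reducing CV folds from {folds} to {folds_eff}")
    for attempt in range(max_redraw):
        labels = rng.permutation(np.arange(n) % folds_eff)
        if all(events[labels == k].sum() > 0 for k in range(folds_eff)):
            if attempt:
                logger.warning("fold assignment redrawn %d time(s) to avoid event-free folds", attempt)
            return labels, folds_eff
    raise RuntimeError("could not find a fold assignment with events in every fold")


def coxnet_cv_select(
    X,
    y: SurvivalResponse,
    config: ElasticNetConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CVSelection:
    """Two-level (alpha, lambda) selection by cross-validated deviance.

    CV error for a path point is the Verweij-van-Houwelingen cross-validated
    deviance: summed over folds, -2 * [loglik(full data at fold-out fit) -
    loglik(training data at fold-out fit)].  The alpha grid includes 0 for
    completeness (its error is computed on the smallest positive alpha's
    lambda grid) but the returned ``best_alpha`` is restricted to alpha > 0.
    """
    config = config or ElasticNetConfig()
    rng = rng or np.random.default_rng(0)
    mat, names = _design_arrays(X)
    n, p = mat.shape
    events = y.event
    labels, folds_eff = _fold_assignment(n, events, config.folds, rng)

    alpha_grid = config.alpha_grid
    cv_error: dict = {}
    lambda_per_alpha: dict = {}
    best = (np.inf, None, None)

    if config.standardize:
        Xs_full, sd_full, ok_full = _standardize(mat)
    else:
        Xs_full, sd_full, ok_full = mat, np.ones(p), mat.std(axis=0) > 0
    m = np.ones(p)
    lam_grid_smallest_pos = None

    for alpha in alpha_grid:
        if alpha > 0:
            lam_max = lambda_max_value(Xs_full, y.time, y.event, alpha, m, n)
            lam_grid = np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.path_length)
            if lam_grid_smallest_pos is None:
                lam_grid_smallest_pos = lam_grid
        else:
            # ridge has no finite lambda_max; borrow the first positive alpha's grid
            lam_max1 = lambda_max_value(Xs_full, y.time, y.event, alpha_grid[1], m, n)
            lam_grid = np.geomspace(lam_max1, lam_max1 * config.lambda_min_ratio, config.path_length)

        errs = np.zeros(lam_grid.size)
        for k in range(folds_eff):
            train = labels != k
            sub = SurvivalResponse(y.time[train], y.event[train])
            path = coxnet_fit_path(mat[train], sub, alpha, config, m, lam_grid)
            for l in range(lam_grid.size):
                beta = path.coefficients[:, l]
                from ._coxph import breslow_loglik

                ll_full = breslow_loglik(mat @ beta, y.time, y.event)
                ll_train = breslow_loglik(mat[train] @ beta, y.time[train], y.event[train])
                errs[l] += -2.0 * (ll_full - ll_train)
        for l, lam in enumerate(lam_grid):
            cv_error[(float(alpha), float(lam))] = float(errs[l])
        l_best = int(np.argmin(errs))
        lambda_per_alpha[float(alpha)] = float(lam_grid[l_best])
        if alpha > 0 and errs[l_best] < best[0]:
            best = (errs[l_best], float(alpha), float(lam_grid[l_best]))

    if best[1] is None:
        raise RuntimeError("no admissible (alpha > 0) CV solution found")
    return CVSelection(cv_error, best[1], best[2], lambda_per_alpha)
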