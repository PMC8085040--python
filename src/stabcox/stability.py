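"""Stability selection over subsamples with randomized-lasso weakness.

Variable selection is repeated on B random half-subsamples of the derivation
data; each run perturbs the per-feature penalties by multipliers
``m_j = 1 / W_j`` with ``W_j ~ Uniform[weakness, 1]`` (the randomized-lasso
"weakness").  A feature's stability path is its selection frequency along a
fixed lambda grid; the stable set is read off at the penalty ``lambda*``
chosen so that the expected number of falsely selected features stays below
the per-comparison error budget via the bound

    E(V) <= q^2 / ((2*pi_thr - 1) * p)

where ``q`` is the average number of selected features per subsample at
``lambda*`` and ``pi_thr`` the selection-frequency threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cohort import SurvivalResponse
from .coxnet import (
    ElasticNetConfig,
    coxnet_fit_path,
    coxnet_cv_select,
    _design_arrays,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityConfig",
    "StabilityPath",
    "StableSelection",
    "stability_path",
    "select_stable",
    "StabilitySelection",
    "StabilitySelectionResults",
]


@dataclass
class StabilityConfig:
    """B subsamples, weakness, PCER budget and selection threshold."""

    n_subsamples: int = 100
    weakness: float = 0.8
    pcer: float = 0.1
    threshold: float = 0.6
    subsample_fraction: float = 0.5
    weakness_distribution: str = "uniform"  # or "two-point"
    cumulative: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.weakness <= 1:
            raise ValueError("weakness must be in (0, 1]")
        if not 0 < self.pcer < 1:
            raise ValueError("pcer must be in (0, 1)")
        if not 0.5 < self.threshold < 1:
            raise ValueError("threshold must be in (0.5, 1): the error bound needs 2*pi - 1 > 0")
        if not 0 < self.subsample_fraction < 1:
            raise ValueError("subsample_fraction must be in (0, 1)")
        if self.weakness_distribution not in ("uniform", "two-point"):
            raise ValueError("weakness_distribution must be 'uniform' or 'two-point'")


@dataclass
class StabilityPath:
    """Per-feature selection frequencies along the lambda grid.

    ``frequency[j, l]`` is the fraction of subsamples in which feature j had a
    nonzero coefficient at ``lambdas[l]`` (a multiple of 1/B);
    ``mean_selected[l]`` is the average active-set size per subsample, i.e.
    the column sum of ``frequency``.
    """

    lambdas: np.ndarray
    frequency: np.ndarray
    mean_selected: np.ndarray
    alpha_used: float
    n_subsamples: int
    feature_names: list[str] | None = None
    n_fits: np.ndarray | None = None  # subsamples that solved each grid point

    def to_long_frame(self):
        import pandas as pd

        p, L = self.frequency.shape
        names = self.feature_names or [f"x{j}" for j in range(p)]
        recs = [
            {"feature": names[j], "ln_lambda": float(np.log(self.lambdas[l])),
             "frequency": float(self.frequency[j, l])}
            for j in range(p) for l in range(L)
        ]
        return pd.DataFrame(recs)


@dataclass
class StableSelection:
    """PCER-controlled stable set at the chosen penalty."""

    chosen_lambda: float
    chosen_index: int
    q_max: float
    q_at_chosen: float
    stable_features: dict
    threshold: float
    bound_attainable: bool = True

    def to_json_dict(self) -> dict:
        return {
            "chosen_lambda": self.chosen_lambda,
            "q_max": self.q_max,
            "q_at_chosen": self.q_at_chosen,
            "threshold": self.threshold,
            "bound_attainable": self.bound_attainable,
            "stable_features": {str(k): float(v) for k, v in self.stable_features.items()},
        }


def stability_path(
    X,
    y: SurvivalResponse,
    alpha: float,
    lambdas,
    config: StabilityConfig | None = None,
    rng: np.random.Generator | None = None,
    en_config: ElasticNetConfig | None = None,
) -> StabilityPath:
    """Selection frequencies over B weakness-randomized subsample fits.

    ``lambdas`` must be the grid precomputed on the full derivation data at
    the chosen alpha, so that frequencies across subsamples refer to the same
    penalties.  Subsamples with zero events are redrawn (at most
    10*B redraws in total).
    """
    config = config or StabilityConfig()
    en_config = en_config or ElasticNetConfig()
    rng = rng or np.random.default_rng(0)
    mat, names = _design_arrays(X)
    n, p = mat.shape
    lambdas = np.asarray(lambdas, float)
    B = config.n_subsamples
    size = int(np.floor(n * config.subsample_fraction))
    counts = np.zeros((p, lambdas.size))
    mean_active = np.zeros(lambdas.size)
    n_fits = np.zeros(lambdas.size, dtype=int)
    redraws = 0
    for b in range(B):
        while True:
            idx = rng.choice(n, size=size, replace=False)
            if y.event[idx].sum() > 0:
                break
            redraws += 1
            logger.warning("subsample %d had zero events; redrawn", b)
            if redraws > 10 * B:
                raise RuntimeError("too many event-free subsamples")
        if config.weakness_distribution == "uniform":
            W = rng.uniform(config.weakness, 1.0, size=p)
        else:
            W = np.where(rng.random(p) < 0.5, config.weakness, 1.0)
        m = 1.0 / W
        sub = SurvivalResponse(y.time[idx], y.event[idx])
        path = coxnet_fit_path(mat[idx], sub, alpha, en_config, m, lambdas)
        active = path.coefficients != 0
        if config.cumulative:
            active = np.cumsum(active, axis=1) > 0
        counts += active
        mean_active += active.sum(axis=0)
        n_fits[: path.n_computed or lambdas.size] += 1
    freq = counts / B
    return StabilityPath(lambdas, freq, mean_active / B, alpha, B, names, n_fits)


def select_stable(path: StabilityPath, config: StabilityConfig, p: int | None = None) -> StableSelection:
    """Choose lambda* under the per-comparison error budget and threshold.

    ``q_max = p * sqrt(pcer * (2*threshold - 1))`` bounds the admissible
    average selection count; lambda* is the smallest grid lambda whose
    q(lambda) still respects the bound (scanning from the largest penalty).
    If even the largest penalty violates the bound, lambda* falls back to it
    with a warning.  The stable set collects features whose selection
    frequency at lambda* reaches the threshold.
    """
    if p is None:
        p = path.frequency.shape[0]
    q_max = p * np.sqrt(config.pcer * (2 * config.threshold - 1))
    q = path.mean_selected.copy()
    if path.n_fits is not None:
        # grid points not solved by every subsample (dfmax stop) cannot
        # certify the bound; exclude them from the scan
        q[path.n_fits < path.n_subsamples] = np.inf
    admissible = np.nonzero(q <= q_max)[0]
    attainable = True
    if admissible.size == 0:
        logger.warning("q exceeds q_max at every grid point; falling back to lambda_max")
        chosen = 0
        attainable = False
    else:
        chosen = int(admissible.max())  # smallest admissible lambda (grid is decreasing)
    names = path.feature_names or [f"x{j}" for j in range(path.frequency.shape[0])]
    stable = {
        names[j]: float(path.frequency[j, chosen])
        for j in np.nonzero(path.frequency[:, chosen] >= config.threshold)[0]
    }
    return StableSelection(float(path.lambdas[chosen]), chosen, float(q_max),
                           float(q[chosen]), stable, config.threshold, attainable)


class StabilitySelection:
    """Stability-selected elastic-net Cox model for one outcome.

    Parameters
    ----------
    X : EncodedDesign, DataFrame or ndarray
        Fully numeric design (derivation subjects only).
    y : SurvivalResponse
        Outcome for the derivation subjects.
    alpha : float, optional
        Elastic-net mixing parameter.  When omitted, it is chosen by the
        two-level cross-validation rule at fit time.
    config, en_config
        Stability and solver/CV controls.

    ``fit(rng)`` runs (optionally) the CV alpha selection, computes the
    full-data lambda grid, then the subsample stability path and the
    PCER-controlled stable set, returning a
    :class:`StabilitySelectionResults`.
    """

    def __init__(self, X, y: SurvivalResponse, alpha: float | None = None,
                 config: StabilityConfig | None = None,
                 en_config: ElasticNetConfig | None = None):
        self.X = X
        self.y = y
        self.alpha = alpha
        self.config = config or StabilityConfig()
        self.en_config = en_config or ElasticNetConfig()

    def fit(self, rng: np.random.Generator | None = None) -> "StabilitySelectionResults":
        rng = rng or np.random.default_rng(0)
        cv = None
        alpha = self.alpha
        if alpha is None:
            cv = coxnet_cv_select(self.X, self.y, self.en_config, rng)
            alpha = cv.best_alpha
        full_path = coxnet_fit_path(self.X, self.y, alpha, self.en_config)
        path = stability_path(self.X, self.y, alpha, full_path.lambdas,
                              self.config, rng, self.en_config)
        selection = select_stable(path, self.config)
        signs = {}
        names = path.feature_names or [f"x{j}" for j in range(full_path.coefficients.shape[0])]
        # effect direction at lambda*: sign of the full-data elastic-net coefficient
        for feat in selection.stable_features:
            j = names.index(feat)
            coef_row = full_path.coefficients[j]
            c = coef_row[selection.chosen_index]
            if c == 0:  # fall back to the first nonzero along the path
                nz = coef_row[coef_row != 0]
                c = nz[0] if nz.size else 0.0
            signs[feat] = int(np.sign(c))
        return StabilitySelectionResults(self, alpha, cv, full_path, path, selection, signs)


class StabilitySelectionResults:
    """Fitted stability selection: paths, stable set and effect directions."""

    def __init__(self, model, alpha, cv, full_path, path, selection, signs):
        self.model = model
        self.alpha = alpha
        self.cv = cv
        self.full_path = full_path
        self.path = path
        self.selection = selection
        self.derivation_signs = signs

    @property
    def stable_features(self) -> dict:
        return self.selection.stable_features

    def summary(self):
        """Per-feature table: maximum frequency, frequency at lambda*, stability."""
        import pandas as pd

        names = self.path.feature_names or [f"x{j}" for j in range(self.path.frequency.shape[0])]
        chosen = self.selection.chosen_index
        df = pd.DataFrame({
            "feature": names,
            "max_frequency": self.path.frequency.max(axis=1),
            "frequency_at_lambda": self.path.frequency[:, chosen],
        })
        df["stable"] = df["frequency_at_lambda"] >= self.selection.threshold
        df["sign"] = [self.derivation_signs.get(f, 0) for f in names]
        return df.sort_values("frequency_at_lambda", ascending=False).reset_index(drop=True)
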