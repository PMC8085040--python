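"""Incident/dynamic time-dependent AUC with bootstrap out-of-bag evaluation.

Discrimination of a risk score is summarized at each event time t as the
probability that a subject dying at t (incident case) outranks a subject
still at risk after t (dynamic control), with tied scores counting 1/2.  A
model's out-of-sample curve is obtained by refitting it on bootstrap
resamples of the cohort, scoring the out-of-bag subjects, evaluating the AUC
at their event times, and averaging the values within each month of
follow-up.  Missing predictor values for multivariable models are filled by
marginal random imputation (draws from each variable's observed values),
repeated M times with the per-imputation curves averaged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coxph import newton_cox, ConvergenceError
from .cohort import CauseCode, CohortTable, SurvivalResponse
from .encoding import quintile_groups, transform_values
from .stats import cause_specific_outcome

logger = logging.getLogger(__name__)

__all__ = [
    "TDROCConfig",
    "OutcomeModelSpec",
    "TimeAUCCurve",
    "incident_dynamic_auc",
    "impute_random",
    "bootstrap_oob_auc",
]


@dataclass
class TDROCConfig:
    n_bootstrap: int = 1000
    n_imputations: int = 25
    horizon_months: int = 48
    min_oob_events_per_month: int = 1

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1 or self.n_imputations < 1:
            raise ValueError("n_bootstrap and n_imputations must be >= 1")


@dataclass
class OutcomeModelSpec:
    """A Cox model recipe: outcome plus (variable, transform, form) terms.

    ``form`` is ``linear`` (transformed value as-is), ``high-quintile-indicator``
    (top-fifth dummy with thresholds from the full input cohort) or
    ``spline-df4`` (penalized spline with 4 effective degrees of freedom).
    """

    outcome: object  # CauseCode or "all-cause"
    predictors: list  # of (variable, transform, form)
    label: str = ""

    _FORMS = ("linear", "high-quintile-indicator", "spline-df4")

    def __post_init__(self) -> None:
        for _, _, form in self.predictors:
            if form not in self._FORMS:
                raise ValueError(f"unknown predictor form {form!r}")


@dataclass
class TimeAUCCurve:
    """Per-month averaged out-of-bag AUC (missing where nothing contributed)."""

    month: np.ndarray
    mean_auc: np.ndarray
    n_reps_contributing: np.ndarray
    per_imputation_auc: np.ndarray | None = None
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"model_label": self.label, "month": self.month,
                           "mean_auc": self.mean_auc,
                           "n_reps": self.n_reps_contributing})
        return df


def incident_dynamic_auc(scores, y: SurvivalResponse, eval_times=None):
    """Incident/dynamic AUC at each evaluation time.

    At time t, cases are subjects with an event exactly at t and controls are
    subjects still at risk strictly after t; AUC(t) is the fraction of
    case-control pairs ranked correctly by the score (ties count 1/2).  Times
    with no case or no control yield NaN, not an error.

    Returns ``(times, aucs)`` arrays.
    """
    scores = np.asarray(scores, float)
    time, event = y.time, y.event
    if eval_times is None:
        eval_times = np.unique(time[event == 1])
    eval_times = np.asarray(eval_times, float)
    aucs = np.full(eval_times.size, np.nan)
    for i, t in enumerate(eval_times):
        cases = scores[(time == t) & (event == 1)]
        controls = scores[time > t]
        if cases.size == 0 or controls.size == 0:
            continue
        greater = (cases[:, None] > controls[None, :]).sum()
        ties = (cases[:, None] == controls[None, :]).sum()
        aucs[i] = (greater + 0.5 * ties) / (cases.size * controls.size)
    return eval_times, aucs


def impute_random(cohort: CohortTable, M: int, rng: np.random.Generator) -> list[CohortTable]:
    """M marginal random imputations of the cohort's predictor columns.

    Each missing entry is replaced, independently per imputation, by a
    uniform draw from the variable's observed values.  A fully missing
    variable raises an error naming it.
    """
    completed = []
    names = cohort.predictor_names
    for name in names:
        if cohort.data[name].dropna().empty:
            raise ValueError(f"variable {name!r} has no observed values to impute from")
    for _ in range(M):
        df = cohort.data.copy()
        for name in names:
            col = df[name]
            miss = col.isna()
            if miss.any():
                pool = col.dropna().to_numpy()
                df.loc[miss, name] = rng.choice(pool, size=int(miss.sum()), replace=True)
        completed.append(CohortTable(df, list(cohort.schema), cohort.below_lod))
    return completed


class _ModelBuilder:
    """Turns an OutcomeModelSpec into design columns for arbitrary subjects.

    Quintile thresholds are frozen on the full input cohort; spline terms are
    refit per call (each bootstrap resample gets its own smoothing) while the
    basis is anchored on the full cohort's observed range.
    """

    def __init__(self, spec: OutcomeModelSpec, cohort: CohortTable, rng):
        from .spline import PSplineConfig, _pspline_basis

        self.spec = spec
        self.cohort = cohort
        self.high_cuts: dict[str, float] = {}
        self.bases: dict[str, object] = {}
        self.spline_sizes: dict[str, int] = {}
        for var, transform, form in spec.predictors:
            if form == "high-quintile-indicator":
                _, thr = quintile_groups(cohort.data[var], rng, var)
                self.high_cuts[var] = thr.high_cut
            elif form == "spline-df4":
                vals = transform_values(cohort.data[var], transform, var).dropna()
                basis, K = _pspline_basis(vals.to_numpy(), PSplineConfig(target_df=4.0))
                self.bases[var] = basis
                self.spline_sizes[var] = K

    def required_columns(self) -> list[str]:
        return [var for var, _, _ in self.spec.predictors]

    def complete_mask(self, df: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(df), dtype=bool)
        for var in self.required_columns():
            mask &= ~df[var].isna().to_numpy()
        return mask

    def design_and_penalty(self, df: pd.DataFrame):
        """Design matrix plus block penalty layout for spline terms."""
        from scipy.linalg import null_space

        from .spline import _difference_penalty

        cols = []
        blocks = []  # (start, size, penalty matrix) for penalized spline blocks
        start = 0
        for var, transform, form in self.spec.predictors:
            vals = transform_values(df[var], transform, var).to_numpy(dtype=float)
            if form == "linear":
                cols.append(vals[:, None])
                start += 1
            elif form == "high-quintile-indicator":
                raw = df[var].to_numpy(dtype=float)
                with np.errstate(invalid="ignore"):
                    cols.append((raw > self.high_cuts[var]).astype(float)[:, None])
                start += 1
            else:  # spline-df4
                K = self.spline_sizes[var]
                B = self.bases[var](vals)
                Z = null_space(np.ones((1, K)))
                P = Z.T @ _difference_penalty(K, 2) @ Z
                Bt = B @ Z
                cols.append(Bt)
                blocks.append((start, K - 1, P))
                start += K - 1
        return np.hstack(cols), blocks


def _fit_spec_model(X, blocks, y: SurvivalResponse, target_df=4.0):
    """Fit the Cox model, tuning each spline block to its target df.

    Monotone-likelihood resamples (e.g. a perfectly separating marker) fall
    back to a weak ridge so the rep still yields a usable risk ordering.
    """
    p = X.shape[1]
    if not blocks:
        try:
            beta, _, _ = newton_cox(X, y.time, y.event)
        except ConvergenceError:
            ridge = np.eye(p) * max(1.0, float(np.mean(X * X)))
            beta, _, _ = newton_cox(X, y.time, y.event, penalty=ridge)
        return beta
    # single shared smoothing search per block (bisection on ln-lambda)
    def fit_at(loglams, beta0=None):
        pen = np.zeros((p, p))
        for (s, size, P), ll in zip(blocks, loglams):
            pen[s:s + size, s:s + size] = np.exp(ll) * P
        beta, _, info = newton_cox(X, y.time, y.event, penalty=pen, beta0=beta0)
        F = np.linalg.solve(info + pen, info)
        edfs = [float(np.trace(F[s:s + size, s:s + size])) for s, size, _ in blocks]
        return beta, edfs

    loglams = [2.0] * len(blocks)
    beta = None
    for b in range(len(blocks)):
        lo, hi = -10.0, 20.0
        for _ in range(30):
            loglams[b] = 0.5 * (lo + hi)
            try:
                beta, edfs = fit_at(loglams, beta)
            except ConvergenceError:
                lo = loglams[b]
                continue
            if abs(edfs[b] - target_df) < 0.05:
                break
            if edfs[b] > target_df:
                lo = loglams[b]
            else:
                hi = loglams[b]
    if beta is None:
        beta, _ = fit_at(loglams)
    return beta


def bootstrap_oob_auc(
    spec: OutcomeModelSpec,
    cohort: CohortTable,
    config: TDROCConfig | None = None,
    rng: np.random.Generator | None = None,
) -> TimeAUCCurve:
    """Bootstrap out-of-bag incident/dynamic AUC, averaged per month.

    For each bootstrap rep the model is fit on a with-replacement resample
    and out-of-bag subjects are scored by their linear predictor; AUC values
    at OOB event times are assigned to month ``ceil(t)`` and averaged over
    all (rep, event time) contributions.  With missing predictor values, M
    marginal imputations are run and their curves averaged (per-imputation
    curves are retained).  Reps whose fit fails are skipped and counted; more
    than 20% failures raises.
    """
    config = config or TDROCConfig()
    rng = rng or np.random.default_rng(0)
    builder = _ModelBuilder(spec, cohort, rng)
    needed = builder.required_columns()
    any_missing = cohort.data[needed].isna().any().any()

    if any_missing:
        datasets = impute_random(cohort, config.n_imputations, rng)
    else:
        datasets = [cohort]

    months = np.arange(1, config.horizon_months + 1)
    per_imp = np.full((len(datasets), months.size), np.nan)
    per_imp_n = np.zeros((len(datasets), months.size), dtype=int)

    for m_idx, dataset in enumerate(datasets):
        y_all = cause_specific_outcome(dataset, spec.outcome)
        X_all, blocks = builder.design_and_penalty(dataset.data)
        n = dataset.n
        sums = np.zeros(months.size)
        counts = np.zeros(months.size, dtype=int)
        rep_contrib = np.zeros(months.size, dtype=int)
        skipped = 0
        for b in range(config.n_bootstrap):
            idx = rng.choice(n, size=n, replace=True)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size == 0:
                continue
            y_boot = SurvivalResponse(y_all.time[idx], y_all.event[idx])
            if y_boot.n_events == 0:
                skipped += 1
                continue
            try:
                beta = _fit_spec_model(X_all[idx], blocks, y_boot)
            except (ConvergenceError, np.linalg.LinAlgError):
                skipped += 1
                continue
            scores = X_all[oob] @ beta
            y_oob = SurvivalResponse(y_all.time[oob], y_all.event[oob])
            times, aucs = incident_dynamic_auc(scores, y_oob)
            ok = ~np.isnan(aucs)
            if not ok.any():
                continue
            mo = np.ceil(times[ok]).astype(int)
            keep = (mo >= 1) & (mo <= config.horizon_months)
            np.add.at(sums, mo[keep] - 1, aucs[ok][keep])
            np.add.at(counts, mo[keep] - 1, 1)
            contrib = np.unique(mo[keep]) - 1
            rep_contrib[contrib] += 1
        if skipped > 0.2 * config.n_bootstrap:
            raise RuntimeError(f"{skipped} of {config.n_bootstrap} bootstrap fits failed")
        with np.errstate(invalid="ignore"):
            per_imp[m_idx] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        per_imp_n[m_idx] = rep_contrib

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_auc = np.nanmean(per_imp, axis=0)
    n_reps = per_imp_n.sum(axis=0)
    mean_auc[n_reps == 0] = np.nan
    return TimeAUCCurve(months, mean_auc, n_reps,
                        per_imp if len(datasets) > 1 else None, spec.label)
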