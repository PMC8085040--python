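"""Classical survival estimators and tests.

Covers the descriptive/confirmatory layer of the workflow: cause-specific
outcome construction (competing deaths censored), univariate Cox confirmation
with Efron ties and Wald inference, chi-squared / Mann-Whitney balance tests,
Aalen-Johansen cumulative incidence, the log-rank test for trend over ordered
groups, and the formatted baseline and confirmation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CauseCode, CohortTable, SurvivalResponse

__all__ = [
    "TestResult",
    "CoxSummary",
    "CIFCurve",
    "cause_specific_outcome",
    "cox_univariate",
    "chi2_test",
    "mann_whitney_test",
    "cif_estimate",
    "logrank_trend_test",
    "confirmation_table",
    "baseline_table",
]


@dataclass
class TestResult:
    statistic: float
    df: int | None
    p: float
    method: str


@dataclass
class CoxSummary:
    """One univariate Cox confirmation row (hazard ratio, Wald CI/p, flags).

    ``flag`` is ``"*"`` for two-sided p < 0.05, ``"#"`` for p < 0.1 with the
    same effect direction as seen in the derivation elastic net, else ``""``.
    """

    coefficient: float
    hr: float
    ci95: tuple[float, float]
    wald_p: float
    n_nonzero: int
    flag: str = ""
    converged: bool = True


@dataclass
class CIFCurve:
    """Aalen-Johansen cumulative incidence per cause per group."""

    times: dict
    incidence: dict  # (group, cause) -> np.ndarray aligned with times[(group, cause)]


def cause_specific_outcome(cohort: CohortTable, target) -> SurvivalResponse:
    """Build the cause-specific (or all-cause) survival response.

    For a specific cause, deaths from competing causes are censored at their
    death time (cause-specific hazard convention).  ``target`` may be a
    :class:`CauseCode` or the string ``"all-cause"``.
    """
    cause = cohort.cause
    if target in ("all-cause", "all", None):
        event = (cause != CauseCode.CENSORED).astype(int)
    else:
        target = CauseCode(target)
        if target == CauseCode.CENSORED:
            raise ValueError("target cause must be a death cause or 'all-cause'")
        event = (cause == int(target)).astype(int)
    if event.sum() == 0:
        warnings.warn("outcome has zero events; unfit for Cox regression")
    return SurvivalResponse(cohort.time, event)


def _wald_flag(p: float, sign: float, derivation_sign) -> str:
    if p < 0.05:
        return "*"
    if p < 0.1 and derivation_sign is not None and np.sign(sign) == np.sign(derivation_sign):
        return "#"
    return ""


def cox_univariate(x, y: SurvivalResponse, derivation_sign=None) -> CoxSummary:
    """Univariate Cox regression with Efron ties and Wald 95% CI / p-value.

    Monotone-likelihood fits (e.g. a dummy group with zero events) are
    reported as degenerate rows with HR 0 or inf, CI (0, inf) and p close to
    1 instead of raising.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        raise ValueError("constant predictor")
    if y.n_events == 0:
        raise ValueError("no events in outcome")
    df = pd.DataFrame({"x": x, "time": y.time, "event": y.event})
    n_nonzero = int((x != 0).sum())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter = CoxPHFitter()
            fitter.fit(df, duration_col="time", event_col="event")
        coef = float(fitter.params_["x"])
        se = float(fitter.standard_errors_["x"])
        p = float(fitter.summary.loc["x", "p"])
        if not np.isfinite(se) or abs(coef) > 15:
            raise ConvergenceError("monotone likelihood")
        lo, hi = float(np.exp(coef - 1.959963984540054 * se)), float(np.exp(coef + 1.959963984540054 * se))
        return CoxSummary(coef, float(np.exp(coef)), (lo, hi), p, n_nonzero,
                          _wald_flag(p, coef, derivation_sign))
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        # direction of divergence: no events among carriers -> HR 0
        carriers_events = int(y.event[x > np.median(x)].sum())
        others_events = int(y.event[x <= np.median(x)].sum())
        hr = 0.0 if carriers_events <= others_events else np.inf
        coef = -np.inf if hr == 0.0 else np.inf
        return CoxSummary(coef, hr, (0.0, np.inf), 0.998, n_nonzero, "", converged=False)


def chi2_test(counts) -> TestResult:
    """Pearson chi-squared homogeneity test; Yates correction for 2x2 tables."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        warnings.warn("zero margin in contingency table; returning p = 1")
        return TestResult(0.0, None, 1.0, "chi2")
    correction = counts.shape == (2, 2)
    res = sps.chi2_contingency(counts, correction=correction)
    return TestResult(float(res.statistic), int(res.dof), float(res.pvalue),
                      "chi2-yates" if correction else "chi2")


def mann_whitney_test(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution for small tie-free samples and the
    tie/continuity-corrected normal approximation otherwise (scipy's
    ``method="auto"`` rule).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(float(res.statistic), None, float(res.pvalue), "mann-whitney")


def cif_estimate(time, cause, groups=None) -> CIFCurve:
    """Aalen-Johansen cause-specific cumulative incidence, optionally by group.

    ``groups`` is a label per subject; empty groups are omitted with a
    warning.  Returns step-function values at the sorted event times.
    """
    from lifelines import AalenJohansenFitter

    time = np.asarray(time, dtype=float)
    cause = np.asarray(cause, dtype=int)
    if groups is None:
        groups = np.zeros(time.size, dtype=int)
    if isinstance(groups, pd.Categorical) or (
            hasattr(groups, "dtype") and isinstance(groups.dtype, pd.CategoricalDtype)):
        levels = list(pd.Categorical(groups).categories)
        groups = np.asarray(pd.Categorical(groups))
    else:
        groups = np.asarray(groups)
        levels = list(pd.unique(groups))
    times_out: dict = {}
    inc: dict = {}
    for g in levels:
        mask = groups == g
        if mask.sum() == 0:
            warnings.warn(f"empty group {g!r} omitted from CIF")
            continue
        for k in (CauseCode.CARDIOVASCULAR, CauseCode.INFECTION, CauseCode.OTHER):
            if (cause[mask] == int(k)).sum() == 0:
                times_out[(g, int(k))] = np.array([])
                inc[(g, int(k))] = np.array([])
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ajf = AalenJohansenFitter(calculate_variance=False)
                ajf.fit(time[mask], cause[mask], event_of_interest=int(k))
            curve = ajf.cumulative_density_
            times_out[(g, int(k))] = curve.index.to_numpy(dtype=float)
            inc[(g, int(k))] = curve.iloc[:, 0].to_numpy(dtype=float)
    return CIFCurve(times_out, inc)


def logrank_trend_test(y: SurvivalResponse, group_labels, scores=None) -> TestResult:
    """Log-rank test for trend across ordered groups (1 df score test).

    The observed-minus-expected event-count vector over groups is contrasted
    with equally spaced scores (or user scores); its hypergeometric variance
    is accumulated over event times.  With two groups this reduces exactly to
    the standard two-sample log-rank test.
    """
    labels = pd.Categorical(group_labels)
    g_levels = list(labels.categories)
    G = len(g_levels)
    if G < 2:
        raise ValueError("trend test requires at least 2 ordered groups")
    if scores is None:
        scores = np.arange(G, dtype=float)
    scores = np.asarray(scores, dtype=float)
    gidx = np.asarray(labels.codes)
    time, event = y.time, y.event

    order = np.argsort(time, kind="stable")
    t_s, e_s, g_s = time[order], event[order], gidx[order]
    OmE = np.zeros(G)
    V = np.zeros((G, G))
    n_at_risk = np.array([(g_s == g).sum() for g in range(G)], dtype=float)
    i = 0
    n = t_s.size
    while i < n:
        j = i
        d_g = np.zeros(G)
        leave_g = np.zeros(G)
        while j < n and t_s[j] == t_s[i]:
            leave_g[g_s[j]] += 1
            if e_s[j] == 1:
                d_g[g_s[j]] += 1
            j += 1
        d = d_g.sum()
        N = n_at_risk.sum()
        if d > 0 and N > 1:
            frac = n_at_risk / N
            OmE += d_g - d * frac
            mult = d * (N - d) / (N - 1)
            V += mult * (np.diag(frac) - np.outer(frac, frac))
        n_at_risk -= leave_g
        i = j
    num = float(scores @ OmE)
    den = float(scores @ V @ scores)
    if den <= 0:
        return TestResult(0.0, 1, 1.0, "logrank-trend")
    stat = num * num / den
    return TestResult(stat, 1, float(sps.chi2.sf(stat, 1)), "logrank-trend")


def confirmation_table(
    stable: dict,
    cohort_confirm: CohortTable,
    design_confirm,
    derivation_signs: dict | None = None,
) -> pd.DataFrame:
    """Per-outcome univariate Cox confirmation of the stable features.

    ``stable`` maps an outcome label (``"all-cause"`` or a :class:`CauseCode`)
    to its stable feature selection; each stable feature is tested only
    against the outcome(s) it was selected for, on the confirmation subjects
    only.  Row-level fit failures become degenerate rows, never aborting the
    table.
    """
    derivation_signs = derivation_signs or {}
    rows = []
    for outcome, selection in stable.items():
        features = getattr(selection, "stable_features", selection)
        y = cause_specific_outcome(cohort_confirm, outcome)
        for feat in features:
            x = design_confirm.frame[feat].to_numpy(dtype=float)
            sign = derivation_signs.get((outcome, feat), derivation_signs.get(feat))
            try:
                s = cox_univariate(x, y, derivation_sign=sign)
            except ValueError as exc:
                rows.append({"outcome": str(outcome), "feature": feat, "hr": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "n": int((x != 0).sum()), "flag": "", "note": str(exc)})
                continue
            rows.append({"outcome": str(outcome), "feature": feat, "hr": s.hr,
                         "ci_low": s.ci95[0], "ci_high": s.ci95[1], "p": s.wald_p,
                         "n": s.n_nonzero, "flag": s.flag,
                         "note": "" if s.converged else "non-convergent"})
    cols = ["outcome", "feature", "hr", "ci_low", "ci_high", "p", "n", "flag", "note"]
    return pd.DataFrame(rows, columns=cols)


def format_count_percent(count: int, total: int) -> str:
    return f"{count} ({int(np.floor(100 * count / total + 0.5))}%)"


def baseline_table(cohort: CohortTable, assignment, matching) -> pd.DataFrame:
    """Baseline characteristics table with balance p-values.

    Quantitative variables are summarized as median [IQR], nominal ones as
    count (percent, nearest integer); the p-value column comes from the same
    tests used for split matching.
    """
    from .split import split_pvalues

    assignment = np.asarray(assignment, dtype=bool)
    pvals = split_pvalues(cohort, assignment, matching)
    rows = []

    def _summarize(values: pd.Series, kind: str) -> str:
        obs = values.dropna()
        if obs.empty:
            return "- [-]"
        if kind == "nominal":
            return format_count_percent(int((obs != 0).sum()), len(values))
        med = obs.median()
        q1, q3 = obs.quantile([0.25, 0.75])
        return f"{med:g} [{q1:g}-{q3:g}]"

    groups = {"total": np.ones(cohort.n, dtype=bool), "derivation": assignment,
              "confirmation": ~assignment}
    for var in matching:
        col = cohort.data[var.name]
        row = {"variable": var.name}
        for gname, mask in groups.items():
            row[gname] = _summarize(col[mask], var.kind)
        row["p"] = pvals.get(var.name, np.nan)
        rows.append(row)
    from .split import _mortality_indicators

    for name, indicator in _mortality_indicators(cohort).items():
        ser = pd.Series(indicator, index=cohort.data.index, dtype=float)
        row = {"variable": name}
        for gname, mask in groups.items():
            row[gname] = _summarize(ser[mask], "nominal")
        row["p"] = pvals.get(name, np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=["variable", "total", "derivation", "confirmation", "p"])
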