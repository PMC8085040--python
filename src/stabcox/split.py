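"""Matched random splitting of a cohort into derivation and confirmation sets.

The procedure is a pure random search: draw many random 2/3:1/3 assignments,
test the two groups for balance on a list of matching variables (chi-squared
for nominal, Mann-Whitney for quantitative, with mortality indicators always
tested as nominal), and keep the split whose *smallest* matching p-value is
largest (maximin balance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import CohortTable, CauseCode, VariableSchema
from . import stats as _stats

__all__ = ["SplitAssignment", "split_pvalues", "best_matched_split"]

#: month horizon used for the early-mortality matching indicator
ONE_YEAR_MONTHS = 12.0


@dataclass
class SplitAssignment:
    """One derivation/confirmation assignment with its balance p-values."""

    derivation_flags: np.ndarray
    ratio: float
    matching_pvalues: dict[str, float]
    min_p: float

    @property
    def n_derivation(self) -> int:
        return int(self.derivation_flags.sum())

    @property
    def n_confirmation(self) -> int:
        return int((~self.derivation_flags).sum())

    def to_frame(self, cohort: CohortTable):
        import pandas as pd

        return pd.DataFrame(
            {"set": np.where(self.derivation_flags, "derivation", "confirmation")},
            index=cohort.subject_ids,
        )


def _mortality_indicators(cohort: CohortTable) -> dict[str, np.ndarray]:
    cause = cohort.cause
    time = cohort.time
    return {
        "all_cause_mortality": (cause != CauseCode.CENSORED).astype(int),
        "cardiovascular_mortality": (cause == CauseCode.CARDIOVASCULAR).astype(int),
        "infection_mortality": (cause == CauseCode.INFECTION).astype(int),
        "other_mortality": (cause == CauseCode.OTHER).astype(int),
        "one_year_mortality": ((cause != CauseCode.CENSORED) & (time <= ONE_YEAR_MONTHS)).astype(int),
    }


def split_pvalues(
    cohort: CohortTable,
    assignment: np.ndarray,
    matching: list[VariableSchema],
    include_mortality: bool = True,
) -> dict[str, float]:
    """Balance p-values between the two halves of an assignment.

    Nominal matching variables use the chi-squared test, quantitative ones the
    Mann-Whitney test (missing values excluded).  The five mortality
    indicators (all-cause, three causes, one-year) are event counts and are
    always tested as nominal 2x2 tables when ``include_mortality`` is set.
    """
    assignment = np.asarray(assignment, dtype=bool)
    if assignment.all() or (~assignment).all():
        raise ValueError("both split groups must be non-empty")
    pvals: dict[str, float] = {}
    for var in matching:
        if var.name not in cohort.data.columns:
            raise ValueError(f"matching variable {var.name!r} absent from cohort")
        col = cohort.data[var.name]
        if var.kind == "nominal":
            pvals[var.name] = _nominal_p(col.to_numpy(dtype=float), assignment)
        else:
            a = col[assignment].dropna().to_numpy(dtype=float)
            b = col[~assignment].dropna().to_numpy(dtype=float)
            if a.size == 0 or b.size == 0:
                pvals[var.name] = 1.0  # degenerate (no observed spread to test)
            else:
                pvals[var.name] = _stats.mann_whitney_test(a, b).p
    if include_mortality:
        for name, indicator in _mortality_indicators(cohort).items():
            pvals[name] = _nominal_p(indicator.astype(float), assignment)
    return pvals


def _nominal_p(values: np.ndarray, assignment: np.ndarray) -> float:
    ok = ~np.isnan(values)
    levels = np.unique(values[ok])
    if levels.size < 2:
        return 1.0  # degenerate variable: perfectly balanced by definition
    counts = np.zeros((2, levels.size), dtype=int)
    for g, grp_mask in enumerate((assignment, ~assignment)):
        sel = values[grp_mask & ok]
        for k, lev in enumerate(levels):
            counts[g, k] = int((sel == lev).sum())
    return _stats.chi2_test(counts).p


def best_matched_split(
    cohort: CohortTable,
    n_splits: int = 1000,
    ratio: float = 2.0 / 3.0,
    matching: list[VariableSchema] | None = None,
    rng: np.random.Generator | None = None,
    include_mortality: bool = True,
    keep_all: bool = False,
) -> SplitAssignment:
    """Maximin-balance random split search.

    Draws ``n_splits`` uniformly random assignments with derivation size
    ``round(ratio * n)`` and returns the one maximizing the minimum matching
    p-value (ties broken by first occurrence).  With ``keep_all`` the full
    min-p distribution is attached as ``assignment.all_min_p`` for diagnostics.
    """
    if cohort.n < 10:
        raise ValueError("cohort too small to split (n < 10)")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    if matching is None:
        matching = [s for s in cohort.schema if s.matching_variable]
    n = cohort.n
    n_deriv = int(np.floor(ratio * n + 0.5))

    best: SplitAssignment | None = None
    all_min_p: list[float] = []
    for _ in range(n_splits):
        flags = np.zeros(n, dtype=bool)
        flags[rng.choice(n, size=n_deriv, replace=False)] = True
        pvals = split_pvalues(cohort, flags, matching, include_mortality)
        min_p = min(pvals.values()) if pvals else 1.0
        all_min_p.append(min_p)
        if best is None or min_p > best.min_p:
            best = SplitAssignment(flags, ratio, pvals, min_p)
    assert best is not None
    if keep_all:
        best.all_min_p = np.asarray(all_min_p)  # type: ignore[attr-defined]
    return best
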