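"""Classical estimators and tests: Cox confirmation, chi2/MW, CIF, trend."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from conftest import make_exponential_survival
from stabcox.cohort import CauseCode, CohortTable, SurvivalResponse, VariableSchema
from stabcox.stats import (
    baseline_table,
    cause_specific_outcome,
    chi2_test,
    cif_estimate,
    confirmation_table,
    cox_univariate,
    format_count_percent,
    logrank_trend_test,
    mann_whitney_test,
)


# ---------------------------------------------------------------------------
# cause-specific outcomes

def test_cause_specific_event_counts(table1_like_cohort):
    cohort, _ = table1_like_cohort
    assert cause_specific_outcome(cohort, "all-cause").n_events == 169
    assert cause_specific_outcome(cohort, CauseCode.CARDIOVASCULAR).n_events == 64
    assert cause_specific_outcome(cohort, CauseCode.INFECTION).n_events == 43
    assert cause_specific_outcome(cohort, CauseCode.OTHER).n_events == 62


def test_competing_deaths_are_censored_at_death_time(table1_like_cohort):
    cohort, _ = table1_like_cohort
    y = cause_specific_outcome(cohort, CauseCode.INFECTION)
    cv = cohort.cause == int(CauseCode.CARDIOVASCULAR)
    assert np.all(y.event[cv] == 0)
    assert np.array_equal(y.time, cohort.time)


def test_zero_event_target_warns():
    data = pd.DataFrame({"time_months": [5.0, 6.0], "cause": [0, 1]})
    cohort = CohortTable(data, [])
    with pytest.warns(UserWarning, match="zero events"):
        cause_specific_outcome(cohort, CauseCode.OTHER)


# ---------------------------------------------------------------------------
# univariate Cox confirmation

def test_cox_univariate_parameter_recovery():
    """Two-group exponential data with true HR 2 recovers ln 2 within 2 SE."""
    rng = np.random.default_rng(8)
    x = rng.integers(0, 2, 2000).astype(float)
    _, y = make_exponential_survival(rng, 2000, np.log(2.0), x=x)
    s = cox_univariate(x, y)
    se = (np.log(s.ci95[1]) - np.log(s.ci95[0])) / (2 * 1.96)
    assert abs(s.coefficient - np.log(2.0)) < 2 * se
    assert s.hr == pytest.approx(np.exp(s.coefficient))


def test_cox_univariate_constant_predictor_errors():
    y = SurvivalResponse(np.arange(1.0, 11.0), np.ones(10, int))
    with pytest.raises(ValueError, match="constant"):
        cox_univariate(np.zeros(10), y)


def test_cox_univariate_degenerate_dummy_reported_not_crashed():
    """A dummy group with zero events yields HR 0, CI (0, inf), p ~ 1."""
    rng = np.random.default_rng(3)
    n = 80
    x = np.zeros(n)
    x[:7] = 1.0  # 7 carriers, none with an event
    event = np.zeros(n, int)
    event[30:60] = 1
    y = SurvivalResponse(rng.exponential(10, n) + 0.1, event)
    s = cox_univariate(x, y)
    assert s.hr == 0.0
    assert s.ci95 == (0.0, np.inf)
    assert s.wald_p > 0.9
    assert not s.converged
    assert s.n_nonzero == 7


def test_cox_univariate_flags():
    rng = np.random.default_rng(11)
    x = rng.integers(0, 2, 500).astype(float)
    _, y = make_exponential_survival(rng, 500, 1.0, x=x)
    s = cox_univariate(x, y, derivation_sign=+1)
    assert s.flag == "*"  # strong effect


def test_wald_ci_p_duality():
    """The 95% CI excludes HR=1 exactly when the Wald p is below 0.05."""
    for seed in range(6):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300)
        _, y = make_exponential_survival(rng, 300, 0.15, x=x)
        s = cox_univariate(x, y)
        excludes_one = not (s.ci95[0] <= 1.0 <= s.ci95[1])
        assert excludes_one == (s.wald_p < 0.05)


# ---------------------------------------------------------------------------
# chi-squared

def test_chi2_reproduces_published_pvalues():
    assert round(chi2_test([[112, 205], [57, 101]]).p, 2) == 0.95
    assert round(chi2_test([[27, 290], [16, 142]]).p, 2) == 0.68


def test_chi2_perfect_homogeneity():
    res = chi2_test([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_chi2_zero_margin_warns_p_one():
    with pytest.warns(UserWarning, match="zero margin"):
        res = chi2_test([[0, 0], [5, 7]])
    assert res.p == 1.0


def _yates_oracle(table):
    """Direct textbook computation of the Yates-corrected 2x2 chi-squared."""
    table = np.asarray(table, float)
    rows, cols, n = table.sum(1), table.sum(0), table.sum()
    expected = np.outer(rows, cols) / n
    stat = (np.maximum(np.abs(table - expected) - 0.5, 0.0) ** 2 / expected).sum()
    return sps.chi2.sf(stat, 1)


def test_chi2_matches_formula_oracle_small_tables():
    """All 2x2 tables with n <= 12 and positive margins."""
    checked = 0
    for cells in itertools.product(range(7), repeat=4):
        if sum(cells) > 12:
            continue
        t = np.array(cells).reshape(2, 2)
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            continue
        assert chi2_test(t).p == pytest.approx(_yates_oracle(t), abs=1e-12)
        checked += 1
    assert checked > 100


# ---------------------------------------------------------------------------
# Mann-Whitney

def _mw_exact_oracle(a, b):
    """Exhaustive two-sided permutation distribution of the U statistic."""
    pooled = np.concatenate([a, b])
    na = len(a)
    u_obs = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact").statistic
    us = []
    for comb in itertools.combinations(range(len(pooled)), na):
        mask = np.zeros(len(pooled), bool)
        mask[list(comb)] = True
        u = sps.mannwhitneyu(pooled[mask], pooled[~mask],
                             alternative="two-sided", method="exact").statistic
        us.append(u)
    us = np.asarray(us)
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


def test_mann_whitney_exact_small_sample():
    res = mann_whitney_test([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p == pytest.approx(0.1)  # 2/20 exact two-sided


@pytest.mark.parametrize("seed,na,nb", [(0, 3, 3), (1, 4, 5), (2, 5, 6), (3, 2, 7)])
def test_mann_whitney_matches_enumeration_oracle(seed, na, nb):
    rng = np.random.default_rng(seed)
    vals = rng.permutation(np.arange(1.0, na + nb + 1))  # tie-free
    a, b = vals[:na], vals[na:]
    assert mann_whitney_test(a, b).p == pytest.approx(_mw_exact_oracle(a, b), abs=1e-12)


def test_mann_whitney_identical_samples():
    a = np.array([1.0, 2.0, 3.0, 3.0, 4.0])
    assert mann_whitney_test(a, a.copy()).p >= 0.99


def test_mann_whitney_type_i_error():
    rejections = 0
    reps = 1000
    rng = np.random.default_rng(0)
    for _ in range(reps):
        a, b = rng.normal(size=12), rng.normal(size=12)
        rejections += mann_whitney_test(a, b).p < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rejections / reps - 0.05) < 3 * se


# ---------------------------------------------------------------------------
# cumulative incidence

def test_cif_single_cause_reduces_to_one_minus_km():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(4)
    time = rng.exponential(10, 150) + 0.1
    cause = np.where(rng.random(150) < 0.6, int(CauseCode.CARDIOVASCULAR), 0)
    curve = cif_estimate(time, cause)
    km = KaplanMeierFitter().fit(time, cause > 0)
    t = curve.times[(0, 1)]
    cif = curve.incidence[(0, 1)]
    km_vals = 1 - km.survival_function_at_times(t).to_numpy()
    assert np.allclose(cif, km_vals, atol=1e-10)


def test_cif_no_censoring_final_values_are_death_fractions():
    rng = np.random.default_rng(5)
    n = 200
    time = rng.exponential(10, n) + 0.1
    cause = rng.choice([1, 2], size=n)
    curve = cif_estimate(time, cause)
    for k in (1, 2):
        assert curve.incidence[(0, k)][-1] == pytest.approx((cause == k).mean(), abs=1e-10)


def test_cif_sum_identity_with_overall_km():
    """Sum of cause-specific CIFs equals 1 - overall KM survival."""
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(6)
    n = 300
    time = rng.exponential(10, n) + 0.1
    cause = rng.choice([0, 1, 2, 3], size=n, p=[0.3, 0.3, 0.2, 0.2])
    curve = cif_estimate(time, cause)
    km = KaplanMeierFitter().fit(time, cause > 0)
    check_t = np.quantile(time[cause > 0], [0.2, 0.5, 0.8])
    for t in check_t:
        total = sum(
            curve.incidence[(0, k)][curve.times[(0, k)] <= t][-1]
            if np.any(curve.times[(0, k)] <= t) else 0.0
            for k in (1, 2, 3)
        )
        km_val = float(km.survival_function_at_times([t]).iloc[0])
        assert total == pytest.approx(1 - km_val, abs=1e-8)


def test_cif_empty_group_warns():
    with pytest.warns(UserWarning, match="empty group"):
        cif_estimate(np.array([1.0, 2.0]), np.array([1, 0]),
                     groups=pd.Categorical(["a", "a"], categories=["a", "b"]))


# ---------------------------------------------------------------------------
# log-rank trend

def test_trend_two_groups_equals_standard_logrank():
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(7)
    n = 120
    g = rng.integers(0, 2, n)
    time = rng.exponential(np.where(g == 1, 5, 8)) + 0.05
    event = (rng.random(n) < 0.7).astype(int)
    res = logrank_trend_test(SurvivalResponse(time, event), g)
    ref = logrank_test(time[g == 0], time[g == 1], event[g == 0], event[g == 1])
    assert res.p == pytest.approx(ref.p_value, rel=1e-6)


def test_trend_type_i_error():
    rng = np.random.default_rng(1)
    reps, rejections = 400, 0
    for _ in range(reps):
        g = rng.integers(0, 3, 90)
        time = rng.exponential(5, 90) + 0.05
        event = (rng.random(90) < 0.8).astype(int)
        rejections += logrank_trend_test(SurvivalResponse(time, event), g).p < 0.05
    se = np.sqrt(0.05 * 0.95 / reps)
    assert abs(rejections / reps - 0.05) < 3 * se


def test_trend_power_under_monotone_hazards():
    hits = 0
    for seed in range(15):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, 600)
        mult = np.array([1.0, 1.5, 2.25])[g]
        time = rng.exponential(1 / mult) + 1e-3
        event = np.ones(600, int)
        cens = rng.exponential(2.0, 600)
        event[cens < time] = 0
        time = np.minimum(time, cens) + 1e-6
        hits += logrank_trend_test(SurvivalResponse(time, event), g).p < 0.05
    assert hits >= 12


def test_trend_single_group_errors():
    y = SurvivalResponse(np.arange(1.0, 5.0), np.ones(4, int))
    with pytest.raises(ValueError, match="2 ordered groups"):
        logrank_trend_test(y, np.zeros(4, int))


# ---------------------------------------------------------------------------
# confirmation and baseline tables

def _confirm_setup():
    rng = np.random.default_rng(9)
    n = 150
    x = rng.integers(0, 2, n).astype(float)
    p_inf = np.where(x == 1, 0.5, 0.08)
    cause = np.where(rng.random(n) < p_inf, int(CauseCode.INFECTION), 0)
    cause[(cause == 0) & (rng.random(n) < 0.1)] = int(CauseCode.CARDIOVASCULAR)
    data = pd.DataFrame({"time_months": rng.exponential(20, n) + 0.1,
                         "cause": cause, "marker": x})
    cohort = CohortTable(data, [VariableSchema("marker", "nominal", "indicator")])

    class Design:
        frame = pd.DataFrame({"marker": x})

    return cohort, Design()


def test_confirmation_empty_stable_set_gives_empty_table():
    cohort, design = _confirm_setup()
    table = confirmation_table({CauseCode.INFECTION: {}}, cohort, design)
    assert table.empty


def test_confirmation_tests_only_selected_outcome():
    cohort, design = _confirm_setup()
    stable = {CauseCode.INFECTION: {"marker": 0.8},
              CauseCode.CARDIOVASCULAR: {}}
    table = confirmation_table(stable, cohort, design,
                               {("2", "marker"): +1})
    assert len(table) == 1
    assert table.iloc[0]["outcome"] == "2"
    assert table.iloc[0]["hr"] > 1


def test_format_counts_match_published_percentages():
    assert format_count_percent(331, 475) == "331 (70%)"
    assert format_count_percent(35, 475) == "35 (7%)"
    assert format_count_percent(169, 475) == "169 (36%)"
    assert format_count_percent(112, 317) == "112 (35%)"


def test_baseline_table_shapes(table1_like_cohort):
    cohort, flags = table1_like_cohort
    matching = [s for s in cohort.schema if s.matching_variable]
    table = baseline_table(cohort, flags, matching)
    assert {"variable", "total", "derivation", "confirmation", "p"} <= set(table.columns)
    allcause = table[table["variable"] == "all_cause_mortality"].iloc[0]
    assert allcause["total"] == "169 (36%)"
    assert allcause["derivation"] == "112 (35%)"
    assert round(allcause["p"], 2) == 0.95


def test_baseline_table_all_missing_placeholder():
    data = pd.DataFrame({"time_months": np.full(20, 10.0), "cause": np.zeros(20, int),
                         "gap": np.full(20, np.nan)})
    cohort = CohortTable(data, [VariableSchema("gap", "quantitative", "linear")])
    flags = np.arange(20) < 13
    table = baseline_table(cohort, flags, cohort.schema)
    assert table[table["variable"] == "gap"].iloc[0]["total"] == "- [-]"
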