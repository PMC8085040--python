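"""Incident/dynamic AUC, marginal imputation and bootstrap OOB curves."""

import numpy as np
import pandas as pd
import pytest

from stabcox.cohort import CauseCode, CohortTable, SurvivalResponse, VariableSchema
from stabcox.tdroc import (
    OutcomeModelSpec,
    TDROCConfig,
    bootstrap_oob_auc,
    impute_random,
    incident_dynamic_auc,
)


def _marker_cohort(rng, n=120, strength=2.0, miss=0.0):
    x = rng.normal(size=n)
    eta = strength * x
    T = rng.exponential(1.0 / np.exp(eta)) * 12
    time = np.minimum(np.maximum(T, 1e-3), 48.0)
    cause = np.where(T <= 48.0, int(CauseCode.CARDIOVASCULAR), 0)
    vals = x.copy()
    if miss > 0:
        vals[rng.random(n) < miss] = np.nan
    data = pd.DataFrame({"time_months": time, "cause": cause, "marker": vals},
                        index=pd.RangeIndex(n, name="subject_id"))
    return CohortTable(data, [VariableSchema("marker", "quantitative", "linear")])


class TestIncidentDynamicAUC:
    def test_perfect_ranking_gives_auc_one(self):
        rng = np.random.default_rng(0)
        time = rng.permutation(np.arange(1.0, 41.0))
        y = SurvivalResponse(time, np.ones(40, int))
        _, aucs = incident_dynamic_auc(-time, y)
        assert np.all(aucs[~np.isnan(aucs)] == 1.0)
        # last event time has no controls -> undefined, not an error
        assert np.isnan(aucs[-1])

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(1)
        time = np.round(rng.exponential(5, 10) + 0.5, 1)
        event = rng.integers(0, 2, 10)
        event[0] = 1
        scores = rng.normal(size=10)
        y = SurvivalResponse(time, event)
        times, aucs = incident_dynamic_auc(scores, y)
        for t, auc in zip(times, aucs):
            num = den = 0.0
            for i in range(10):
                if not (time[i] == t and event[i] == 1):
                    continue
                for j in range(10):
                    if time[j] > t:
                        den += 1
                        num += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
            expected = num / den if den else np.nan
            if np.isnan(expected):
                assert np.isnan(auc)
            else:
                assert auc == pytest.approx(expected)

    def test_invariant_under_monotone_score_transform(self):
        rng = np.random.default_rng(2)
        time = rng.exponential(5, 50) + 0.1
        event = rng.integers(0, 2, 50)
        event[:5] = 1
        scores = rng.normal(size=50)
        y = SurvivalResponse(time, event)
        _, a1 = incident_dynamic_auc(scores, y)
        _, a2 = incident_dynamic_auc(np.exp(3 * scores), y)
        np.testing.assert_array_equal(a1, a2)

    def test_null_scores_average_half(self):
        rng = np.random.default_rng(3)
        vals = []
        for _ in range(300):
            time = rng.exponential(5, 60) + 0.1
            event = (rng.random(60) < 0.7).astype(int)
            scores = rng.normal(size=60)
            _, aucs = incident_dynamic_auc(scores, SurvivalResponse(time, event))
            vals.extend(aucs[~np.isnan(aucs)])
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.5) < 3 * se


class TestImputeRandom:
    def test_no_missing_gives_identical_copies(self):
        rng = np.random.default_rng(0)
        cohort = _marker_cohort(rng)
        out = impute_random(cohort, 3, rng)
        for c in out:
            pd.testing.assert_frame_equal(c.data, cohort.data)

    def test_output_length_default_M(self):
        rng = np.random.default_rng(1)
        cohort = _marker_cohort(rng, miss=0.2)
        assert len(impute_random(cohort, 25, rng)) == 25

    def test_marginal_frequency_preserved(self):
        """Binary column 70% positive among observed: imputed draws match."""
        rng = np.random.default_rng(2)
        n = 40
        binary = np.r_[np.ones(28), np.zeros(12)]
        vals = binary.copy()
        vals[5] = np.nan
        data = pd.DataFrame({"time_months": np.full(n, 10.0),
                             "cause": np.zeros(n, int), "b": vals},
                            index=pd.RangeIndex(n, name="subject_id"))
        cohort = CohortTable(data, [VariableSchema("b", "nominal", "indicator")])
        observed_pos = pd.Series(vals).dropna().mean()
        draws = [impute_random(cohort, 1, np.random.default_rng(s))[0].data.loc[5, "b"]
                 for s in range(2000)]
        assert np.mean(draws) == pytest.approx(observed_pos, abs=0.03)

    def test_fully_missing_variable_errors(self):
        data = pd.DataFrame({"time_months": [1.0, 2.0], "cause": [0, 0],
                             "gone": [np.nan, np.nan]})
        cohort = CohortTable(data, [VariableSchema("gone", "quantitative", "linear")])
        with pytest.raises(ValueError, match="gone"):
            impute_random(cohort, 2, np.random.default_rng(0))


class TestBootstrapOOB:
    def test_perfectly_separable_marker_gives_auc_near_one(self):
        """With death time a deterministic decreasing function of the marker,
        every OOB case outranks every control, so AUC is 1 at every time."""
        rng = np.random.default_rng(4)
        n = 120
        x = rng.normal(size=n)
        T = 30.0 * np.exp(-x)  # deterministic, strictly decreasing in x
        time = np.minimum(T, 48.0)
        cause = np.where(T <= 48.0, int(CauseCode.CARDIOVASCULAR), 0)
        data = pd.DataFrame({"time_months": time, "cause": cause, "marker": x},
                            index=pd.RangeIndex(n, name="subject_id"))
        cohort = CohortTable(data, [VariableSchema("marker", "quantitative", "linear")])
        spec = OutcomeModelSpec("all-cause", [("marker", "none", "linear")], "separable")
        curve = bootstrap_oob_auc(spec, cohort, TDROCConfig(n_bootstrap=100),
                                  np.random.default_rng(0))
        good = curve.mean_auc[(curve.n_reps_contributing >= 5) & ~np.isnan(curve.mean_auc)]
        assert good.size > 0
        assert np.all(good >= 0.95)

    def test_strong_beats_null_marker(self):
        wins = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            cohort = _marker_cohort(rng, n=120, strength=1.5)
            cohort.data["noise"] = rng.normal(size=120)
            cohort.schema.append(VariableSchema("noise", "quantitative", "linear"))
            cfg = TDROCConfig(n_bootstrap=40)
            strong = bootstrap_oob_auc(
                OutcomeModelSpec("all-cause", [("marker", "none", "linear")]),
                cohort, cfg, np.random.default_rng(seed))
            null = bootstrap_oob_auc(
                OutcomeModelSpec("all-cause", [("noise", "none", "linear")]),
                cohort, cfg, np.random.default_rng(seed))
            mask = ~np.isnan(strong.mean_auc[:12]) & ~np.isnan(null.mean_auc[:12])
            wins += np.nanmean(strong.mean_auc[:12][mask]) > np.nanmean(null.mean_auc[:12][mask])
        assert wins >= 7

    def test_full_resample_contributes_nothing(self):
        """A bootstrap rep containing every subject has an empty OOB set."""
        rng = np.random.default_rng(5)
        cohort = _marker_cohort(rng, n=2)

        class AllInRng:
            def __init__(self):
                self._inner = np.random.default_rng(0)

            def choice(self, n, size=None, replace=True):
                return np.array([0, 1])

            def __getattr__(self, name):
                return getattr(self._inner, name)

        spec = OutcomeModelSpec("all-cause", [("marker", "none", "linear")])
        curve = bootstrap_oob_auc(spec, cohort, TDROCConfig(n_bootstrap=1), AllInRng())
        assert np.all(np.isnan(curve.mean_auc))
        assert np.all(curve.n_reps_contributing == 0)

    def test_imputation_paths_retained(self):
        rng = np.random.default_rng(6)
        cohort = _marker_cohort(rng, n=100, strength=2.0, miss=0.15)
        spec = OutcomeModelSpec("all-cause", [("marker", "none", "linear")])
        cfg = TDROCConfig(n_bootstrap=10, n_imputations=4)
        curve = bootstrap_oob_auc(spec, cohort, cfg, np.random.default_rng(0))
        assert curve.per_imputation_auc.shape == (4, 48)

    def test_month_binning_in_range(self):
        rng = np.random.default_rng(7)
        cohort = _marker_cohort(rng, n=100)
        spec = OutcomeModelSpec("all-cause", [("marker", "none", "linear")])
        curve = bootstrap_oob_auc(spec, cohort, TDROCConfig(n_bootstrap=15),
                                  np.random.default_rng(1))
        assert curve.month[0] == 1 and curve.month[-1] == 48
        observed = curve.mean_auc[~np.isnan(curve.mean_auc)]
        assert np.all((observed >= 0) & (observed <= 1))
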