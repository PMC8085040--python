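"""Shared fixtures: small constructed cohorts and simulation helpers."""

import numpy as np
import pandas as pd
import pytest

from stabcox.cohort import CauseCode, CohortTable, SurvivalResponse, VariableSchema


def make_exponential_survival(rng, n, log_hr, x=None, censor_scale=2.0, time_scale=1.0):
    """Two-arm / linear-predictor exponential survival data."""
    if x is None:
        x = rng.normal(size=n)
    eta = np.asarray(x) @ np.asarray(log_hr) if np.ndim(x) == 2 else np.asarray(x) * log_hr
    T = rng.exponential(1.0 / np.exp(eta))
    C = rng.exponential(censor_scale, n)
    time = np.maximum(np.minimum(T, C), 1e-4) * time_scale
    event = (T <= C).astype(int)
    return x, SurvivalResponse(time, event)


@pytest.fixture(scope="session")
def table1_like_cohort():
    """A 475-subject cohort whose mortality counts match the dialysis study's
    derivation/confirmation table: derivation (first 317 rows) has 44 CV, 27
    infection, 41 other deaths (24 within the first year); confirmation has
    20 / 16 / 21 (11 within a year)."""
    n_deriv, n_conf = 317, 158

    def build(n, cv, inf, oth, early):
        cause = np.zeros(n, dtype=int)
        cause[:cv] = int(CauseCode.CARDIOVASCULAR)
        cause[cv:cv + inf] = int(CauseCode.INFECTION)
        cause[cv + inf:cv + inf + oth] = int(CauseCode.OTHER)
        time = np.full(n, 48.0)
        deaths = cv + inf + oth
        time[:deaths] = 24.0
        time[:early] = 6.0  # the first `early` deaths happen within a year
        return time, cause

    t_d, c_d = build(n_deriv, 44, 27, 41, 24)
    t_c, c_c = build(n_conf, 20, 16, 21, 11)
    rng = np.random.default_rng(0)
    n = n_deriv + n_conf
    data = pd.DataFrame({
        "time_months": np.concatenate([t_d, t_c]),
        "cause": np.concatenate([c_d, c_c]),
        "age": rng.normal(65, 12, n).round(1),
        "sex": rng.integers(0, 2, n).astype(float),
    }, index=pd.RangeIndex(n, name="subject_id"))
    schema = [
        VariableSchema("age", "quantitative", "linear", "decades", matching_variable=True),
        VariableSchema("sex", "nominal", "indicator", matching_variable=True),
    ]
    cohort = CohortTable(data, schema)
    derivation_flags = np.zeros(n, dtype=bool)
    derivation_flags[:n_deriv] = True
    return cohort, derivation_flags
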