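"""Quintile dummy coding of a mixed-type cohort into a numeric design matrix.

Quantitative predictors are replaced by two indicator columns flagging
membership in the top or bottom fifth of the *total* study population (the
thresholds deliberately come from the full cohort, not the derivation subset).
Ties at a quintile boundary are resolved at random so that the "high" and
"low" groups have exactly ``round(n_observed / 5)`` members.  Missing values,
and values in the middle three quintiles, contribute 0 to both dummies;
missing nominal values fall into the reference category.  Age-like variables
may instead enter linearly (e.g. per decade).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableSchema

__all__ = [
    "QuintileThresholds",
    "EncodedDesign",
    "transform_values",
    "quintile_groups",
    "encode_cohort",
]


def transform_values(values, transform: str, name: str = "<variable>"):
    """Apply a marginal transform, preserving missing values.

    ``ln`` natural log (observed values must be positive), ``asinh`` inverse
    hyperbolic sine (defined at 0, used for assays with below-LOD floors),
    ``decades`` divide by ten (age), ``none`` identity.
    """
    arr = pd.Series(values, dtype=float)
    if transform == "none":
        out = arr
    elif transform == "ln":
        observed = arr.dropna()
        if (observed <= 0).any():
            raise ValueError(f"ln transform of non-positive value in variable {name!r}")
        out = np.log(arr)
    elif transform == "asinh":
        out = np.arcsinh(arr)
    elif transform == "decades":
        out = arr / 10.0
    else:
        raise ValueError(f"unknown transform {transform!r}")
    if isinstance(values, pd.Series):
        return pd.Series(np.asarray(out, dtype=float), index=values.index, name=values.name)
    return np.asarray(out, dtype=float)


@dataclass
class QuintileThresholds:
    """Boundary values and group quota for one variable's quintile coding."""

    variable: str
    low_cut: float
    high_cut: float
    quota: int
    n_observed: int

    def __post_init__(self) -> None:
        if self.n_observed >= 5 and self.low_cut > self.high_cut:
            raise ValueError(f"{self.variable}: low_cut exceeds high_cut")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def quintile_groups(values, rng: np.random.Generator, variable: str = "<variable>"):
    """Label each subject ``low`` / ``mid`` / ``high`` / ``missing`` by quintile rank.

    Exactly ``quota = round(n_observed/5)`` observed subjects receive each of
    the ``high`` and ``low`` labels; subjects tied at the boundary value are
    drawn at random (via ``rng``) to fill the quota, and the two groups are
    always disjoint.

    Returns ``(labels, QuintileThresholds)`` where labels is an object array
    aligned with ``values``.
    """
    ser = pd.Series(values, dtype=float)
    arr = ser.to_numpy()
    observed = np.nonzero(~np.isnan(arr))[0]
    n_obs = observed.size
    if n_obs < 5:
        raise ValueError(f"{variable}: fewer than 5 observed values ({n_obs})")
    quota = _round_half_up(n_obs / 5)

    vals = arr[observed]
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    low_cut = float(sorted_vals[quota - 1])
    high_cut = float(sorted_vals[n_obs - quota])

    labels = np.full(arr.shape, "missing", dtype=object)
    labels[observed] = "mid"

    taken = np.zeros(n_obs, dtype=bool)  # indexes into `observed`

    def _fill(side: str) -> None:
        if side == "high":
            definite = np.nonzero(vals > high_cut)[0]
            tied = np.nonzero((vals == high_cut) & ~taken)[0]
        else:
            definite = np.nonzero((vals < low_cut) & ~taken)[0]
            tied = np.nonzero((vals == low_cut) & ~taken)[0]
        definite = definite[~taken[definite]]
        need = quota - definite.size
        if need < 0:  # cannot happen for high; guard for degenerate low overlap
            definite = definite[:quota]
            need = 0
        pick = rng.choice(tied, size=need, replace=False) if need > 0 else np.array([], dtype=int)
        members = np.concatenate([definite, pick]).astype(int)
        taken[members] = True
        labels[observed[members]] = side

    # fill high first so that with massive ties the groups stay disjoint
    _fill("high")
    _fill("low")

    thresholds = QuintileThresholds(variable, low_cut, high_cut, quota, n_obs)
    if isinstance(values, pd.Series):
        labels = pd.Series(labels, index=values.index)
    return labels, thresholds


@dataclass
class EncodedDesign:
    """Fully numeric n x p design with a column -> source-variable mapping.

    ``column_meta`` has one row per design column with its source variable and
    level tag (``high`` / ``low`` / ``indicator`` / ``linear``).
    """

    frame: pd.DataFrame
    column_meta: pd.DataFrame
    thresholds: dict = field(default_factory=dict)

    @property
    def matrix(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def p(self) -> int:
        return self.frame.shape[1]

    def subset(self, mask) -> "EncodedDesign":
        mask = np.asarray(mask, dtype=bool)
        return EncodedDesign(self.frame.loc[mask].copy(), self.column_meta.copy(), self.thresholds)

    def to_csv(self, path) -> None:
        """Write the matrix as CSV with a commented column-meta header block."""
        with open(path, "w") as fh:
            for _, row in self.column_meta.iterrows():
                fh.write(f"# column={row['column']} source={row['source']} level={row['level']}\n")
            self.frame.to_csv(fh, index_label="subject_id")


def encode_cohort(
    cohort: CohortTable,
    schema: list[VariableSchema],
    threshold_source: CohortTable | None = None,
    rng: np.random.Generator | None = None,
) -> EncodedDesign:
    """Encode a cohort against quintile thresholds from ``threshold_source``.

    ``threshold_source`` defaults to ``cohort`` itself; in the discovery
    pipeline it is the total study population while ``cohort`` may be the
    derivation or confirmation subset.  Quintile group membership (including
    random tie resolution) is computed once on the threshold source and then
    looked up for the encoded rows, so derivation and confirmation encodings
    are consistent.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if threshold_source is None:
        threshold_source = cohort
    unmatched = [s.name for s in schema if s.name not in cohort.data.columns]
    unmatched += [s.name for s in schema if s.name not in threshold_source.data.columns]
    if unmatched:
        raise ValueError(f"schema variables missing from cohort: {sorted(set(unmatched))}")

    cols: dict[str, np.ndarray] = {}
    meta: list[dict] = []
    thresholds: dict[str, QuintileThresholds] = {}
    idx = cohort.data.index

    for var in schema:
        if var.encoding == "indicator":
            raw = cohort.data[var.name]
            observed = raw.dropna()
            if observed.empty:
                warnings.warn(f"nominal variable {var.name!r} is all-missing; "
                              "retaining an all-zero reference column")
            col = (raw.fillna(0.0).to_numpy(dtype=float) != 0).astype(float)
            cols[var.name] = col
            meta.append({"column": var.name, "source": var.name, "level": "indicator"})
        elif var.encoding == "linear":
            vals = transform_values(cohort.data[var.name], var.transform, var.name)
            cols[var.name] = np.nan_to_num(vals.to_numpy(dtype=float), nan=0.0)
            meta.append({"column": var.name, "source": var.name, "level": "linear"})
        else:  # quintile-pair
            src_vals = threshold_source.data[var.name]
            labels_src, thr = quintile_groups(src_vals, rng, var.name)
            thresholds[var.name] = thr
            # look up labels for cohort rows present in the threshold source;
            # unseen rows fall back to strict threshold comparison
            labels = pd.Series("missing", index=idx, dtype=object)
            common = idx.intersection(labels_src.index)
            labels.loc[common] = labels_src.loc[common]
            extra = idx.difference(labels_src.index)
            if len(extra):
                v = cohort.data.loc[extra, var.name]
                lab = pd.Series("mid", index=extra, dtype=object)
                lab[v > thr.high_cut] = "high"
                lab[v < thr.low_cut] = "low"
                lab[v.isna()] = "missing"
                labels.loc[extra] = lab
            high = (labels == "high").to_numpy(dtype=float)
            low = (labels == "low").to_numpy(dtype=float)
            cols[f"{var.name}__high"] = high
            cols[f"{var.name}__low"] = low
            meta.append({"column": f"{var.name}__high", "source": var.name, "level": "high"})
            meta.append({"column": f"{var.name}__low", "source": var.name, "level": "low"})

    frame = pd.DataFrame(cols, index=idx)
    return EncodedDesign(frame, pd.DataFrame(meta), thresholds)
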