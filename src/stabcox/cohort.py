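"""Cohort containers, variable schemas and CSV round-trip I/O.

A cohort is a table of subjects with a right-censored survival outcome
(``time_months``, ``cause``) and a mixed set of nominal / quantitative
predictors that may contain missing values.  The cause of death is coded as a
competing-risk category (censored, cardiovascular, infection, other).  A
JSON sidecar describes the type, encoding and transform of every predictor.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CauseCode",
    "CAUSE_ALIASES",
    "VariableSchema",
    "CohortTable",
    "SurvivalResponse",
    "read_cohort_csv",
    "write_cohort_csv",
    "schema_to_json",
    "schema_from_json",
]


class CauseCode(enum.IntEnum):
    """Competing-risk event categories."""

    CENSORED = 0
    CARDIOVASCULAR = 1
    INFECTION = 2
    OTHER = 3


#: accepted text labels for each cause (case-insensitive)
CAUSE_ALIASES = {
    "censored": CauseCode.CENSORED,
    "0": CauseCode.CENSORED,
    "cardiovascular": CauseCode.CARDIOVASCULAR,
    "cv": CauseCode.CARDIOVASCULAR,
    "1": CauseCode.CARDIOVASCULAR,
    "infection": CauseCode.INFECTION,
    "inf": CauseCode.INFECTION,
    "sepsis": CauseCode.INFECTION,
    "2": CauseCode.INFECTION,
    "other": CauseCode.OTHER,
    "unknown": CauseCode.OTHER,
    "3": CauseCode.OTHER,
}

_KINDS = {"nominal", "quantitative"}
_ENCODINGS = {"indicator", "linear", "quintile-pair"}
_TRANSFORMS = {"none", "ln", "asinh", "decades"}


@dataclass
class VariableSchema:
    """Type, encoding and transform declaration for one predictor.

    ``encoding`` decides how the variable enters the design matrix:
    ``indicator`` (nominal 0/1), ``linear`` (quantitative entered as-is after
    the transform; the age case) or ``quintile-pair`` (two dummies flagging
    membership in the top / bottom fifth of the study population).
    """

    name: str
    kind: str
    encoding: str
    transform: str = "none"
    matching_variable: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.encoding not in _ENCODINGS:
            raise ValueError(f"{self.name}: unknown encoding {self.encoding!r}")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"{self.name}: unknown transform {self.transform!r}")
        if self.kind == "nominal" and self.encoding != "indicator":
            raise ValueError(f"{self.name}: nominal variables must use indicator encoding")
        if self.encoding == "linear" and self.kind != "quantitative":
            raise ValueError(f"{self.name}: linear encoding requires a quantitative variable")


@dataclass
class SurvivalResponse:
    """Right-censored outcome: follow-up time in months and a 0/1 event flag."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event must have equal length")
        if np.any(self.time <= 0):
            raise ValueError("all times must be strictly positive")
        if not np.isin(self.event, [0, 1]).all():
            raise ValueError("event must be 0/1")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


@dataclass
class CohortTable:
    """Subjects x variables table with survival outcome and typed predictors.

    ``data`` is indexed by subject id and holds ``time_months``, ``cause``
    (integer :class:`CauseCode`) plus one column per predictor.  ``below_lod``
    optionally flags assay values below the detection limit (stored as 0 in
    ``data``; distinct from missingness, which is ``NaN``).
    """

    data: pd.DataFrame
    schema: list[VariableSchema]
    below_lod: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for col in ("time_months", "cause"):
            if col not in self.data.columns:
                raise ValueError(f"cohort data must contain a {col!r} column")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated subject ids: {dupes}")
        times = self.data["time_months"].to_numpy(dtype=float)
        if np.any(~np.isfinite(times)) or np.any(times <= 0):
            bad = list(np.nonzero(~(np.isfinite(times) & (times > 0)))[0])
            raise ValueError(f"non-positive follow-up time at rows {bad}")
        causes = self.data["cause"].to_numpy()
        valid = {int(c) for c in CauseCode}
        if not set(np.unique(causes)).issubset(valid):
            raise ValueError("cause column contains values outside CauseCode")
        missing = [s.name for s in self.schema if s.name not in self.data.columns]
        if missing:
            raise ValueError(f"schema variables absent from data: {missing}")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> pd.Index:
        return self.data.index

    @property
    def predictor_names(self) -> list[str]:
        return [s.name for s in self.schema]

    @property
    def time(self) -> np.ndarray:
        return self.data["time_months"].to_numpy(dtype=float)

    @property
    def cause(self) -> np.ndarray:
        return self.data["cause"].to_numpy(dtype=int)

    def subset(self, mask: Sequence[bool] | np.ndarray) -> "CohortTable":
        """Row subset keeping schema and below-LOD flags aligned."""
        mask = np.asarray(mask, dtype=bool)
        lod = self.below_lod.loc[mask] if self.below_lod is not None else None
        return CohortTable(self.data.loc[mask].copy(), list(self.schema), lod)

    def variable(self, name: str) -> pd.Series:
        if name not in self.data.columns:
            raise KeyError(f"unknown variable {name!r}")
        return self.data[name]


# ---------------------------------------------------------------------------
# schema sidecar (JSON)

def schema_to_json(schema: Iterable[VariableSchema]) -> str:
    return json.dumps({"variables": [asdict(s) for s in schema]}, indent=2)


def schema_from_json(text: str) -> list[VariableSchema]:
    payload = json.loads(text)
    return [VariableSchema(**rec) for rec in payload["variables"]]


# ---------------------------------------------------------------------------
# cohort CSV round trip

_LOD_PREFIX = "below_lod__"


def write_cohort_csv(cohort: CohortTable, path: str | Path, schema_path: str | Path) -> None:
    """Write the cohort as a flat CSV plus a JSON schema sidecar.

    Below-LOD flags are stored as companion ``below_lod__<name>`` 0/1 columns
    so the file stays a plain single-table CSV.
    """
    df = cohort.data.copy()
    df.insert(1, "cause_label", [CauseCode(c).name.lower() for c in cohort.cause])
    if cohort.below_lod is not None:
        for name in cohort.below_lod.columns:
            df[_LOD_PREFIX + name] = cohort.below_lod[name].astype(int)
    df = df.drop(columns=["cause"])
    df.to_csv(path, index_label="subject_id")
    Path(schema_path).write_text(schema_to_json(cohort.schema))


def read_cohort_csv(path: str | Path, schema_path: str | Path) -> CohortTable:
    """Read a cohort CSV + schema sidecar, validating outcome columns.

    Raises ``ValueError`` naming the offending rows for unknown cause labels,
    non-positive times or duplicated subject ids.
    """
    schema = schema_from_json(Path(schema_path).read_text())
    df = pd.read_csv(path, index_col="subject_id")
    if df.index.has_duplicates:
        rows = list(np.nonzero(df.index.duplicated())[0] + 2)  # 1-based + header
        raise ValueError(f"duplicated subject_id at file rows {rows}")
    if "cause_label" in df.columns:
        labels = df["cause_label"].astype(str).str.strip().str.lower()
        bad = [i + 2 for i, lab in enumerate(labels) if lab not in CAUSE_ALIASES]
        if bad:
            raise ValueError(f"unknown cause label at file rows {bad}")
        df["cause"] = [int(CAUSE_ALIASES[lab]) for lab in labels]
        df = df.drop(columns=["cause_label"])
    times = df["time_months"].to_numpy(dtype=float)
    bad = [int(i) + 2 for i in np.nonzero(~(np.isfinite(times) & (times > 0)))[0]]
    if bad:
        raise ValueError(f"non-positive time_months at file rows {bad}")
    lod_cols = [c for c in df.columns if c.startswith(_LOD_PREFIX)]
    below = None
    if lod_cols:
        below = df[lod_cols].astype(bool)
        below.columns = [c[len(_LOD_PREFIX):] for c in lod_cols]
        df = df.drop(columns=lod_cols)
    return CohortTable(df, schema, below)
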