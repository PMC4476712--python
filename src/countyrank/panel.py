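"""County panel data model: geographic hierarchy, cell records, CSV I/O,
suppression/censoring rules and survey-to-model transformations.

A :class:`GeoPanel` is the long-format container every other module consumes.
It couples a :class:`GeoHierarchy` (states and the counties nested in them)
with a homogeneous table of observation cells in one of three schemas:

``counts``
    Event counts ``y`` with population denominators ``n`` per county and
    time index ``t`` (-3..0) or age-group index ``a`` (1..9).
``survey_mean``
    Observed survey means (e.g. poor-health days/month) with standard
    errors and respondent counts.
``proportion``
    Proportions with either a survey standard error or an explicit
    numerator/denominator pair (vital-statistics source).

Records are never deleted by suppression rules; they are flagged in a
``suppressed`` column so the county roster survives for downstream ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "PanelValidationError",
    "GeoHierarchy",
    "CountCell",
    "SurveyMeanCell",
    "ProportionCell",
    "GeoPanel",
    "read_panel",
    "write_panel",
    "apply_vital_suppression",
    "apply_brfss_censoring",
    "effective_sample_size",
    "to_log_scale",
]

#: column layout per schema (``suppressed`` is appended on write)
SCHEMA_COLUMNS = {
    "counts": ["state", "county", "fips", "t_or_age", "y", "n"],
    "survey_mean": ["state", "county", "fips", "measure", "mean", "se", "n_resp"],
    "proportion": ["state", "county", "fips", "measure", "p", "se", "y", "n"],
}

#: name of the per-schema index column used for deterministic sort order
_INDEX_COL = {"counts": "t_or_age", "survey_mean": "measure", "proportion": "measure"}


class SchemaError(ValueError):
    """Raised when a CSV lacks required columns or an unknown schema is named."""


class PanelValidationError(ValueError):
    """Raised when rows violate cell invariants; carries offending row numbers."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(f"{message} (rows: {rows})")
        self.rows = rows


@dataclass(frozen=True)
class GeoHierarchy:
    """States and the counties nested within them.

    Counties are identified by the composite key ``(state_id, county_id)``;
    an optional 5-digit FIPS code is carried as an opaque string.
    """

    states: tuple[str, ...]
    counties_by_state: dict[str, tuple[str, ...]]
    fips: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate state identifiers")
        for k in self.states:
            cs = self.counties_by_state.get(k, ())
            if len(cs) < 1:
                raise ValueError(f"state {k!r} has no counties")
            if len(set(cs)) != len(cs):
                raise ValueError(f"duplicate county identifiers in state {k!r}")

    @property
    def county_keys(self) -> list[tuple[str, str]]:
        """All (state, county) pairs in deterministic (state, county) order."""
        return [(k, j) for k in self.states for j in self.counties_by_state[k]]

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_counties(self) -> int:
        return sum(len(v) for v in self.counties_by_state.values())

    def state_index(self) -> dict[str, int]:
        return {k: i for i, k in enumerate(self.states)}

    def county_index(self) -> dict[tuple[str, str], int]:
        return {key: i for i, key in enumerate(self.county_keys)}

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "GeoHierarchy":
        """Infer a hierarchy from ``state``/``county`` (and optional ``fips``) columns."""
        pairs = df[["state", "county"]].drop_duplicates().sort_values(["state", "county"])
        states = tuple(sorted(pairs["state"].unique()))
        cbs = {
            k: tuple(pairs.loc[pairs["state"] == k, "county"])
            for k in states
        }
        fips: dict[tuple[str, str], str] = {}
        if "fips" in df.columns:
            sub = df.dropna(subset=["fips"])
            for s, c, f in zip(sub["state"], sub["county"], sub["fips"]):
                if str(f).strip():
                    fips[(s, c)] = str(f)
        return GeoHierarchy(states=states, counties_by_state=cbs, fips=fips)


@dataclass(frozen=True)
class CountCell:
    """Event count ``y`` over denominator ``n`` at time index t (-3..0) or age index a (1..9)."""

    y: int
    n: float
    t: int

    def __post_init__(self):
        if self.y < 0:
            raise ValueError(f"negative count y={self.y}")
        if self.n <= 0:
            raise ValueError(f"non-positive denominator n={self.n}")
        if self.y > self.n:
            raise ValueError(f"count exceeds denominator: y={self.y} > n={self.n}")


@dataclass(frozen=True)
class SurveyMeanCell:
    """Observed survey mean with its natural-scale standard error.

    ``i`` indexes the measure in a bivariate panel (0 = physical, 1 = mental).
    """

    m_obs: float
    se_obs: float
    n_resp: int
    i: int = 0

    def __post_init__(self):
        if self.m_obs <= 0:
            raise ValueError(f"mean must be positive, got {self.m_obs}")
        if self.se_obs <= 0:
            raise ValueError(f"se must be positive, got {self.se_obs}")


@dataclass(frozen=True)
class ProportionCell:
    """Proportion with survey SE, or explicit counts y/n for vital-statistics sources."""

    p_obs: float
    se_obs: float | None = None
    y: int | None = None
    n: int | None = None
    i: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p_obs <= 1.0):
            raise ValueError(f"proportion out of [0,1]: {self.p_obs}")
        if self.y is not None and self.n:
            if abs(self.p_obs - self.y / self.n) > 1e-9:
                raise ValueError("p_obs inconsistent with y/n")


@dataclass
class GeoPanel:
    """Long-format county observations of one homogeneous cell type."""

    hierarchy: GeoHierarchy
    data: pd.DataFrame
    schema: str
    measure_name: str = ""

    def __post_init__(self):
        if self.schema not in SCHEMA_COLUMNS:
            raise SchemaError(f"unknown schema {self.schema!r}")
        if "suppressed" not in self.data.columns:
            self.data = self.data.assign(suppressed=False)
        missing = set(SCHEMA_COLUMNS[self.schema]) - set(self.data.columns)
        if missing:
            raise SchemaError(f"panel missing columns {sorted(missing)}")
        keys = set(self.hierarchy.county_index())
        bad = [
            i
            for i, (s, c) in enumerate(zip(self.data["state"], self.data["county"]))
            if (s, c) not in keys
        ]
        if bad:
            raise PanelValidationError("county keys not in hierarchy", bad)
        idx = _INDEX_COL[self.schema]
        dup = self.data.duplicated(subset=["state", "county", idx])
        if dup.any():
            raise PanelValidationError(
                "duplicate (county, index) records", list(np.flatnonzero(dup.to_numpy()))
            )

    @property
    def n_records(self) -> int:
        return len(self.data)

    def active(self) -> pd.DataFrame:
        """Records that contribute to a likelihood (not suppressed)."""
        return self.data.loc[~self.data["suppressed"]]

    def sorted_copy(self) -> "GeoPanel":
        idx = _INDEX_COL[self.schema]
        df = self.data.sort_values(["state", "county", idx], kind="mergesort")
        return GeoPanel(self.hierarchy, df.reset_index(drop=True), self.schema, self.measure_name)

    def iter_cells(self):
        """Yield ((state, county), cell) typed records; validates invariants row by row."""
        for _, r in self.data.iterrows():
            key = (r["state"], r["county"])
            if self.schema == "counts":
                yield key, CountCell(y=int(r["y"]), n=float(r["n"]), t=int(r["t_or_age"]))
            elif self.schema == "survey_mean":
                yield key, SurveyMeanCell(
                    m_obs=float(r["mean"]), se_obs=float(r["se"]),
                    n_resp=int(r["n_resp"]), i=int(r["measure"]),
                )
            else:
                y = None if pd.isna(r["y"]) else int(r["y"])
                n = None if pd.isna(r["n"]) else int(r["n"])
                yield key, ProportionCell(
                    p_obs=float(r["p"]),
                    se_obs=None if pd.isna(r["se"]) else float(r["se"]),
                    y=y, n=n, i=int(r["measure"]),
                )


def _validate_rows(df: pd.DataFrame, schema: str) -> None:
    """Row-level invariant checks; reports 0-based data row numbers."""
    bad: list[int] = []
    msg = ""
    if schema == "counts":
        y = pd.to_numeric(df["y"], errors="coerce")
        n = pd.to_numeric(df["n"], errors="coerce")
        mask = y.isna() | n.isna() | (y < 0) | (n <= 0) | (y > n)
        msg = "invalid count cells (need 0 <= y <= n, n > 0)"
        bad = list(np.flatnonzero(mask.to_numpy()))
    elif schema == "survey_mean":
        m = pd.to_numeric(df["mean"], errors="coerce")
        se = pd.to_numeric(df["se"], errors="coerce")
        mask = m.isna() | se.isna() | (m <= 0) | (se <= 0)
        msg = "invalid survey-mean cells (need mean > 0, se > 0)"
        bad = list(np.flatnonzero(mask.to_numpy()))
    else:
        p = pd.to_numeric(df["p"], errors="coerce")
        mask = p.isna() | (p < 0) | (p > 1)
        y = pd.to_numeric(df["y"], errors="coerce")
        n = pd.to_numeric(df["n"], errors="coerce")
        both = y.notna() & n.notna()
        mask |= both & ((y < 0) | (n <= 0) | (y > n))
        msg = "invalid proportion cells (need 0 <= p <= 1 and, if present, 0 <= y <= n)"
        bad = list(np.flatnonzero(mask.to_numpy()))
    if bad:
        raise PanelValidationError(msg, bad)


def read_panel(path, schema: str, measure_name: str = "") -> GeoPanel:
    """Read and validate a county panel CSV.

    Parameters
    ----------
    path : str or file-like
        CSV with a header row; required columns depend on ``schema``.
    schema : {"counts", "survey_mean", "proportion"}
    """
    if schema not in SCHEMA_COLUMNS:
        raise SchemaError(f"unknown schema {schema!r}")
    df = pd.read_csv(
        path,
        dtype={"state": str, "county": str, "fips": str},
        float_precision="round_trip",
    )
    required = [c for c in SCHEMA_COLUMNS[schema] if c != "fips"]
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"CSV missing required columns {sorted(missing)}")
    if "fips" not in df.columns:
        df["fips"] = ""
    df["fips"] = df["fips"].fillna("")
    _validate_rows(df, schema)
    if "suppressed" in df.columns:
        df["suppressed"] = df["suppressed"].astype(bool)
    hierarchy = GeoHierarchy.from_frame(df)
    panel = GeoPanel(hierarchy, df, schema, measure_name=measure_name)
    return panel.sorted_copy()


def write_panel(panel: GeoPanel, path) -> None:
    """Write a panel CSV with deterministic (state, county, index) row order."""
    out = panel.sorted_copy().data
    cols = SCHEMA_COLUMNS[panel.schema] + ["suppressed"]
    out.to_csv(path, index=False, columns=cols)


def apply_vital_suppression(panel: GeoPanel, threshold: int = 5) -> GeoPanel:
    """Flag vital-statistics cells based on ``threshold`` or fewer events.

    Small-count cells (``y <= threshold``, default 5) are marked suppressed so
    they contribute nothing to model likelihoods; the records stay in the
    panel. Idempotent, and commutes with other suppression rules.
    """
    if panel.schema not in ("counts", "proportion"):
        raise SchemaError("vital suppression applies to counts/proportion schemas")
    df = panel.data.copy()
    y = pd.to_numeric(df["y"], errors="coerce")
    flag = y.notna() & (y <= threshold)
    df["suppressed"] = df["suppressed"] | flag
    return GeoPanel(panel.hierarchy, df, panel.schema, panel.measure_name)


def apply_brfss_censoring(
    panel: GeoPanel, min_n: int = 50, rel_width: float = 0.20
) -> GeoPanel:
    """Flag survey cells with few respondents or imprecise estimates.

    A record is suppressed iff its respondent count is below ``min_n`` (default
    50) or its nominal 95% confidence-interval width (2 x 1.96 x SE) exceeds
    ``rel_width`` (default 20%) of the point estimate.
    """
    if panel.schema not in ("survey_mean", "proportion"):
        raise SchemaError("survey censoring applies to survey_mean/proportion schemas")
    df = panel.data.copy()
    if panel.schema == "survey_mean":
        point = df["mean"].astype(float)
        se = df["se"].astype(float)
        nresp = df["n_resp"].astype(float)
    else:
        point = df["p"].astype(float)
        se = pd.to_numeric(df["se"], errors="coerce")
        nresp = pd.to_numeric(df["n"], errors="coerce")
    width = 2.0 * 1.96 * se
    flag = (nresp < min_n) | (width > rel_width * point)
    df["suppressed"] = df["suppressed"] | flag.fillna(False)
    return GeoPanel(panel.hierarchy, df, panel.schema, panel.measure_name)


def effective_sample_size(p_obs: float, se_obs: float) -> tuple[int, int]:
    """Effective binomial sample size implied by a survey proportion and its SE.

    Inverts the binomial variance formula, n = p(1-p)/se^2, rounding to the
    nearest integer (floored at 1); returns ``(n_eff, y_eff)`` with the paired
    pseudo-numerator ``y_eff = round(p_obs * n_eff)``.
    """
    if not (0.0 < p_obs < 1.0):
        raise ValueError("effective sample size undefined for p in {0, 1}")
    if se_obs <= 0:
        raise ValueError("se must be positive")
    n = max(1, round(p_obs * (1.0 - p_obs) / se_obs**2))
    y = round(p_obs * n)
    return int(n), int(y)


def to_log_scale(cell: SurveyMeanCell | tuple[float, float]) -> tuple[float, float]:
    """Map a survey mean and SE to the log scale by the delta method.

    Returns ``(log(m), se/m)``: a first-order (CLT-consistent) approximation
    to the sampling distribution of ``log(m)``.
    """
    if isinstance(cell, SurveyMeanCell):
        m, se = cell.m_obs, cell.se_obs
    else:
        m, se = cell
    if m <= 0:
        raise ValueError("mean must be positive for log transform")
    if se <= 0:
        raise ValueError("se must be positive")
    return math.log(m), se / m
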