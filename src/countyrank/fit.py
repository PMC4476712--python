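"""Model specifications and the four fitting entry points.

Each fitter turns a :class:`~countyrank.panel.GeoPanel` into design arrays
for the nested Laplace engine and returns a :class:`FitResult` holding
fixed-effect estimates with covariance, variance components, and the
empirical-Bayes conditional distribution of every state and county
random-effect block. Suppressed records contribute nothing to the
likelihood; counties with no active records keep a prior EB block
(mean 0, covariance equal to the estimated variance components), so the
full roster survives to the ranking stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .laplace import ConvergenceError, CovStructure, NestedGLMM
from .panel import GeoPanel, effective_sample_size

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "FitResult",
    "fit_cross_sectional",
    "fit_longitudinal",
    "fit_joint_age",
    "fit_joint_bivariate",
    "save_fit",
    "load_fit",
]

FAMILIES = ("poisson", "binomial", "normal_known_variance")
DESIGNS = ("cross_sectional", "longitudinal", "joint_age", "joint_bivariate")


@dataclass(frozen=True)
class ModelSpec:
    """Family + design + ranking direction for one model."""

    family: str
    design: str
    direction: str = "higher_is_worse"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "joint_age" and self.family != "poisson":
            raise ValueError("joint_age design requires the poisson family")
        if self.direction not in ("higher_is_worse", "higher_is_better"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class VarianceComponents:
    """Per-level random-effect covariances with component names."""

    names: tuple[str, ...]
    state_cov: np.ndarray
    county_cov: np.ndarray

    def variances(self, level: str) -> np.ndarray:
        cov = self.state_cov if level == "state" else self.county_cov
        return np.diag(cov).copy()

    def correlation(self, level: str, i: int = 0, j: int = 1) -> float:
        cov = self.state_cov if level == "state" else self.county_cov
        d = np.sqrt(cov[i, i] * cov[j, j])
        return float(cov[i, j] / d) if d > 0 else 0.0


@dataclass
class FitResult:
    """Everything downstream stages need from a fitted model."""

    spec: ModelSpec
    measure_name: str
    fixed_names: tuple[str, ...]
    fixed: np.ndarray
    fixed_cov: np.ndarray
    vc: VarianceComponents
    states: tuple[str, ...]
    roster: tuple[tuple[str, str], ...]  # (state, county) per county, hierarchy order
    county_state: np.ndarray  # (C,) state index per county
    eb_mean_state: np.ndarray  # (K, q)
    eb_cov_state: np.ndarray  # (K, q, q)
    eb_mean_county: np.ndarray  # (C, q)
    eb_cov_county: np.ndarray  # (C, q, q)
    loglik: float
    converged: bool
    grad_norm: float
    n_outer_iter: int
    meta: dict = field(default_factory=dict)

    @property
    def n_counties(self) -> int:
        return len(self.roster)

    def reference_rows(self) -> dict[str, np.ndarray]:
        """Design row per output measure level, at the inferential reference
        point: t = 0 for longitudinal fits, each age group for joint-age,
        each measure for joint-bivariate fits."""
        p = len(self.fixed)
        if self.spec.design in ("cross_sectional", "longitudinal"):
            x = np.zeros(p)
            x[0] = 1.0
            return {self.measure_name or "measure": x}
        if self.spec.design == "joint_age":
            out = {}
            for a in range(1, 10):
                x = np.zeros(p)
                x[0] = 1.0
                if a >= 2:
                    x[a - 1] = 1.0
                out[f"age_{a}"] = x
            return out
        # joint_bivariate
        m0, m1 = self.meta.get("measure_labels", ("measure_0", "measure_1"))
        x0 = np.zeros(p)
        x0[0] = 1.0
        x1 = np.array([1.0, 1.0])
        return {m0: x0, m1: x1}


def _roster_arrays(panel: GeoPanel):
    h = panel.hierarchy
    roster = tuple(h.county_keys)
    cidx = {key: i for i, key in enumerate(roster)}
    sidx = h.state_index()
    county_state = np.array([sidx[s] for s, _ in roster])
    return roster, cidx, sidx, county_state


def _check_active(df: pd.DataFrame, what: str):
    if len(df) == 0:
        raise ValueError(f"no active (non-suppressed) records to fit {what}")


def _run(panel, spec, X, Z, y, aux, county, county_state, struct_c, struct_s,
         fixed_names, measure_name, meta=None, **fit_kw) -> FitResult:
    model = NestedGLMM(
        X=X, Z=Z, y=y, aux=aux, county=county, county_state=county_state,
        family=spec.family, struct_c=struct_c, struct_s=struct_s,
    )
    res = model.fit(**fit_kw)
    if not res.converged:
        raise ConvergenceError(
            f"{spec.design}/{spec.family} fit did not converge "
            f"(gradient sup-norm {res.grad_norm:.3e})",
            grad_norm=res.grad_norm,
        )
    roster, _, _, _ = _roster_arrays(panel)
    vc = VarianceComponents(
        names=tuple(meta.get("re_names", ("intercept",)) if meta else ("intercept",)),
        state_cov=res.cov_state,
        county_cov=res.cov_county,
    )
    return FitResult(
        spec=spec,
        measure_name=measure_name,
        fixed_names=tuple(fixed_names),
        fixed=res.beta,
        fixed_cov=res.beta_cov,
        vc=vc,
        states=tuple(panel.hierarchy.states),
        roster=roster,
        county_state=county_state,
        eb_mean_state=res.u_state,
        eb_cov_state=res.eb_cov_state,
        eb_mean_county=res.u_county,
        eb_cov_county=res.eb_cov_county,
        loglik=res.loglik,
        converged=res.converged,
        grad_norm=res.grad_norm,
        n_outer_iter=res.n_outer_iter,
        meta=meta or {},
    )


def _binomial_columns(df: pd.DataFrame):
    """(y, n) for a proportion slice; survey rows get effective sample sizes."""
    ys, ns = [], []
    for _, r in df.iterrows():
        if pd.notna(r.get("y")) and pd.notna(r.get("n")):
            ys.append(float(r["y"]))
            ns.append(float(r["n"]))
        else:
            n_eff, y_eff = effective_sample_size(float(r["p"]), float(r["se"]))
            ys.append(float(y_eff))
            ns.append(float(n_eff))
    return np.array(ys), np.array(ns)


def fit_cross_sectional(panel: GeoPanel, family: str, measure: int | None = None,
                        direction: str = "higher_is_worse", **fit_kw) -> FitResult:
    """Univariate empty GLMM: intercept plus state and county random intercepts.

    ``measure`` selects one measure index from a bivariate survey/proportion
    panel; counts panels must carry one active record per county (filter the
    time or age index first).
    """
    spec = ModelSpec(family=family, design="cross_sectional", direction=direction)
    roster, cidx, _, county_state = _roster_arrays(panel)
    df = panel.active()
    if measure is not None and "measure" in df.columns:
        df = df.loc[df["measure"].astype(int) == measure]
    _check_active(df, "cross-sectional model")
    county = np.array([cidx[(s, c)] for s, c in zip(df["state"], df["county"])])
    if len(np.unique(county)) != len(county):
        raise ValueError(
            "cross-sectional fit needs one active record per county; "
            "filter the time/age/measure index first"
        )
    if family == "poisson":
        if panel.schema != "counts":
            raise ValueError("poisson family needs a counts panel")
        y = df["y"].to_numpy(float)
        aux = df["n"].to_numpy(float)
    elif family == "binomial":
        if panel.schema != "proportion":
            raise ValueError("binomial family needs a proportion panel")
        y, aux = _binomial_columns(df)
    else:
        if panel.schema != "survey_mean":
            raise ValueError("normal_known_variance family needs a survey_mean panel")
        m = df["mean"].to_numpy(float)
        se = df["se"].to_numpy(float)
        y = np.log(m)
        aux = (se / m) ** 2
    N = len(df)
    X = np.ones((N, 1))
    Z = np.ones((N, 1))
    return _run(
        panel, spec, X, Z, y, aux, county, county_state,
        CovStructure("scalar", 1), CovStructure("scalar", 1),
        fixed_names=("intercept",), measure_name=panel.measure_name,
        meta={"re_names": ("intercept",)}, **fit_kw,
    )


def fit_longitudinal(panel: GeoPanel, direction: str = "higher_is_worse",
                     **fit_kw) -> FitResult:
    """Poisson trend model with correlated random intercepts and slopes.

    The time index t runs over -3..0 with the intercept anchored at t = 0,
    so the intercept (and every EB intercept block) is the current-period
    log rate.
    """
    spec = ModelSpec(family="poisson", design="longitudinal", direction=direction)
    if panel.schema != "counts":
        raise ValueError("longitudinal model needs a counts panel")
    roster, cidx, _, county_state = _roster_arrays(panel)
    df = panel.active()
    _check_active(df, "longitudinal model")
    t = df["t_or_age"].to_numpy(float)
    if len(np.unique(t)) < 2:
        raise ValueError(
            "longitudinal fit needs at least two time points; "
            "use fit_cross_sectional for a single period"
        )
    county = np.array([cidx[(s, c)] for s, c in zip(df["state"], df["county"])])
    y = df["y"].to_numpy(float)
    aux = df["n"].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), t])
    return _run(
        panel, spec, X, X.copy(), y, aux, county, county_state,
        CovStructure("pair", 2), CovStructure("pair", 2),
        fixed_names=("intercept", "year"), measure_name=panel.measure_name,
        meta={"re_names": ("intercept", "year")}, **fit_kw,
    )


def fit_joint_age(panel: GeoPanel, direction: str = "higher_is_worse",
                  **fit_kw) -> FitResult:
    """Joint Poisson model over the nine age groups in one period.

    Age group 1 (<1 year) is the reference; the other eight groups get
    fixed contrasts and independent random slopes at both levels (shared
    random intercept, no cross-age correlations).
    """
    spec = ModelSpec(family="poisson", design="joint_age", direction=direction)
    if panel.schema != "counts":
        raise ValueError("joint-age model needs a counts panel")
    roster, cidx, _, county_state = _roster_arrays(panel)
    df = panel.active()
    _check_active(df, "joint-age model")
    a = df["t_or_age"].to_numpy(int)
    if not np.all((a >= 1) & (a <= 9)):
        raise ValueError("joint-age model expects age indices 1..9")
    county = np.array([cidx[(s, c)] for s, c in zip(df["state"], df["county"])])
    y = df["y"].to_numpy(float)
    aux = df["n"].to_numpy(float)
    N = len(df)
    X = np.zeros((N, 9))
    X[:, 0] = 1.0
    for g in range(2, 10):
        X[a == g, g - 1] = 1.0
    names = ("intercept",) + tuple(f"m{g - 1}" for g in range(2, 10))
    return _run(
        panel, spec, X, X.copy(), y, aux, county, county_state,
        CovStructure("diag", 9), CovStructure("diag", 9),
        fixed_names=names, measure_name=panel.measure_name,
        meta={"re_names": names}, **fit_kw,
    )


def fit_joint_bivariate(panel: GeoPanel, family: str,
                        measure_labels: tuple[str, str] | None = None,
                        direction: str = "higher_is_worse", **fit_kw) -> FitResult:
    """Joint model for a measure pair with correlated (intercept, contrast)
    random blocks at both levels.

    Measure 0 is the reference; measure 1 enters through the fixed contrast
    plus correlated random slopes. ``normal_known_variance`` fits observed
    log means with known sampling variance; ``binomial`` fits logit-linear
    counts, deriving effective sample sizes for survey rows.
    """
    spec = ModelSpec(family=family, design="joint_bivariate", direction=direction)
    if family == "poisson":
        raise ValueError("joint_bivariate supports normal_known_variance or binomial")
    roster, cidx, _, county_state = _roster_arrays(panel)
    df = panel.active()
    _check_active(df, "joint bivariate model")
    i = df["measure"].to_numpy(int)
    if not np.all((i == 0) | (i == 1)):
        raise ValueError("joint bivariate model expects measure indices 0 and 1")
    county = np.array([cidx[(s, c)] for s, c in zip(df["state"], df["county"])])
    if family == "normal_known_variance":
        if panel.schema != "survey_mean":
            raise ValueError("normal_known_variance family needs a survey_mean panel")
        m = df["mean"].to_numpy(float)
        se = df["se"].to_numpy(float)
        y = np.log(m)
        aux = (se / m) ** 2
    else:
        if panel.schema != "proportion":
            raise ValueError("binomial family needs a proportion panel")
        y, aux = _binomial_columns(df)
    X = np.column_stack([np.ones(len(df)), i.astype(float)])
    labels = measure_labels or ("measure_0", "measure_1")
    return _run(
        panel, spec, X, X.copy(), y, aux, county, county_state,
        CovStructure("pair", 2), CovStructure("pair", 2),
        fixed_names=("intercept", "measure"), measure_name=panel.measure_name,
        meta={"re_names": ("intercept", "measure"), "measure_labels": labels},
        **fit_kw,
    )


# ---------------------------------------------------------------------------
# JSON persistence (full numeric precision via repr'd floats in lists)


def save_fit(fit: FitResult, path) -> None:
    doc = {
        "spec": {"family": fit.spec.family, "design": fit.spec.design,
                 "direction": fit.spec.direction},
        "measure_name": fit.measure_name,
        "fixed_names": list(fit.fixed_names),
        "fixed": fit.fixed.tolist(),
        "fixed_cov": fit.fixed_cov.tolist(),
        "vc": {
            "names": list(fit.vc.names),
            "state_cov": fit.vc.state_cov.tolist(),
            "county_cov": fit.vc.county_cov.tolist(),
        },
        "states": list(fit.states),
        "roster": [list(k) for k in fit.roster],
        "county_state": fit.county_state.tolist(),
        "eb_mean_state": fit.eb_mean_state.tolist(),
        "eb_cov_state": fit.eb_cov_state.tolist(),
        "eb_mean_county": fit.eb_mean_county.tolist(),
        "eb_cov_county": fit.eb_cov_county.tolist(),
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "grad_norm": float(fit.grad_norm),
        "n_outer_iter": int(fit.n_outer_iter),
        "meta": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in fit.meta.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_fit(path) -> FitResult:
    with open(path) as fh:
        doc = json.load(fh)
    meta = {k: (tuple(v) if isinstance(v, list) else v) for k, v in doc["meta"].items()}
    return FitResult(
        spec=ModelSpec(**doc["spec"]),
        measure_name=doc["measure_name"],
        fixed_names=tuple(doc["fixed_names"]),
        fixed=np.array(doc["fixed"]),
        fixed_cov=np.array(doc["fixed_cov"]),
        vc=VarianceComponents(
            names=tuple(doc["vc"]["names"]),
            state_cov=np.array(doc["vc"]["state_cov"]),
            county_cov=np.array(doc["vc"]["county_cov"]),
        ),
        states=tuple(doc["states"]),
        roster=tuple((s, c) for s, c in doc["roster"]),
        county_state=np.array(doc["county_state"]),
        eb_mean_state=np.array(doc["eb_mean_state"]),
        eb_cov_state=np.array(doc["eb_cov_state"]),
        eb_mean_county=np.array(doc["eb_mean_county"]),
        eb_cov_county=np.array(doc["eb_cov_county"]),
        loglik=doc["loglik"],
        converged=doc["converged"],
        grad_norm=doc["grad_norm"],
        n_outer_iter=doc["n_outer_iter"],
        meta=meta,
    )
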