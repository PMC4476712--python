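"""Synthetic county panel generators.

Every generator draws from the same generative models the fitting module
estimates — Poisson counts, normal survey means with known sampling
variance, and binomial outcomes, all on top of nested state/county random
intercepts (and, where applicable, correlated random slopes) — and returns
both the observable :class:`~countyrank.panel.GeoPanel` and the latent
ground truth, so parameter- and rank-recovery can be tested end to end.

Default parameter sets mirror the fitted values of the real county health
application (e.g. infant mortality: log-rate intercept about -5.0, county
intercept variance about 0.044), so synthetic panels have realistic scale
and sparsity. County populations are drawn log-uniformly over a wide range
(10^2.5 to 10^6 by default) to create the small-county sparsity that makes
rank inference hard.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GeoHierarchy, GeoPanel, apply_brfss_censoring, apply_vital_suppression

__all__ = [
    "GeneratorParams",
    "generate_hierarchy",
    "simulate_mortality_panel",
    "simulate_survey_means",
    "simulate_binomial_pair",
    "inject_missingness",
    "INFANT_MORTALITY_LONGITUDINAL",
    "INFANT_MORTALITY_CROSS",
    "HEALTH_DAYS_JOINT",
    "FPH_LBW_JOINT",
    "AGE_JOINT",
    "AGE_GROUP_LABELS",
    "NATIONAL_AGE_SHARES",
]

#: nine age groups (<1, 1-4, then 10-year bands to 65-74)
AGE_GROUP_LABELS = (
    "<1", "1-4", "5-14", "15-24", "25-34", "35-44", "45-54", "55-64", "65-74",
)

#: fixed national shares of the under-75 population across the nine groups,
#: used to split a county population into age-group denominators
NATIONAL_AGE_SHARES = np.array(
    [0.014, 0.056, 0.142, 0.144, 0.138, 0.150, 0.146, 0.120, 0.090]
)
NATIONAL_AGE_SHARES = NATIONAL_AGE_SHARES / NATIONAL_AGE_SHARES.sum()


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the nested random-effects generative model.

    ``alpha`` is the fixed intercept on the link scale; ``beta`` the fixed
    slope(s): a scalar per unit time (longitudinal), a scalar measure
    contrast (bivariate), or eight age contrasts (joint-age).  Intercept
    variances ``sigma2_*`` and slope variances ``tau2_*`` live at the state
    and county level; ``rho_*`` are intercept-slope correlations (ignored
    when a level has no slope, must be ``None`` in the joint-age design,
    where slopes are independent across age groups).
    """

    alpha: float
    beta: float | tuple[float, ...] | None = None
    sigma2_state: float = 0.0
    sigma2_county: float = 0.0
    tau2_state: float | tuple[float, ...] | None = None
    tau2_county: float | tuple[float, ...] | None = None
    rho_state: float | None = None
    rho_county: float | None = None
    n_states: int = 51
    counties_per_state: int | tuple[int, int] = 60
    pop_range: tuple[float, float] = (10**2.5, 1e6)

    def __post_init__(self):
        for v in (self.sigma2_state, self.sigma2_county):
            if v < 0:
                raise ValueError("variances must be nonnegative")
        for tau in (self.tau2_state, self.tau2_county):
            if tau is not None and np.any(np.asarray(tau) < 0):
                raise ValueError("slope variances must be nonnegative")
        for r in (self.rho_state, self.rho_county):
            if r is not None and not -1.0 <= r <= 1.0:
                raise ValueError("correlations must lie in [-1, 1]")

    def level_cov(self, level: str) -> np.ndarray:
        """2x2 intercept/slope covariance for one level (scalar-slope designs)."""
        s2 = self.sigma2_state if level == "state" else self.sigma2_county
        t2 = self.tau2_state if level == "state" else self.tau2_county
        rho = self.rho_state if level == "state" else self.rho_county
        if t2 is None:
            return np.array([[s2]])
        t2 = float(np.asarray(t2).reshape(()))
        rho = 0.0 if rho is None else rho
        off = rho * np.sqrt(s2 * t2)
        cov = np.array([[s2, off], [off, t2]])
        # guard against rho = +/-1 rounding the matrix indefinite
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-12:
            raise ValueError("implied covariance block not positive semi-definite")
        return cov


# -- defaults seeded from the real-application fits ---------------------------

INFANT_MORTALITY_LONGITUDINAL = GeneratorParams(
    alpha=-5.01, beta=-0.02,
    sigma2_county=0.044, tau2_county=0.0017, rho_county=0.355,
    sigma2_state=0.038, tau2_state=0.0004, rho_state=0.728,
)

INFANT_MORTALITY_CROSS = GeneratorParams(
    alpha=-5.00, sigma2_county=0.046, sigma2_state=0.039,
)

#: poor physical (reference) / poor mental health days, joint normal model
HEALTH_DAYS_JOINT = GeneratorParams(
    alpha=1.24, beta=-0.07,
    sigma2_county=0.038, tau2_county=0.038, rho_county=-0.313,
    sigma2_state=0.017, tau2_state=0.002, rho_state=0.086,
)

#: fair/poor health prevalence (reference) / low birth weight, joint binomial
FPH_LBW_JOINT = GeneratorParams(
    alpha=-1.70, beta=-0.80,
    sigma2_county=0.069, tau2_county=0.062, rho_county=-0.844,
    sigma2_state=0.066, tau2_state=0.038, rho_state=-0.703,
)

#: joint age-group mortality: intercept = infants, 8 age contrasts,
#: independent per-age random slopes at both levels
AGE_JOINT = GeneratorParams(
    alpha=-4.94,
    beta=(-3.15, -3.71, -2.09, -1.86, -1.25, -0.50, 0.26, 1.11),
    sigma2_county=0.031,
    tau2_county=(0.009, 0.020, 0.061, 0.025, 0.014, 0.006, 0.003, 0.007),
    sigma2_state=0.038,
    tau2_state=(0.023, 0.021, 0.018, 0.018, 0.010, 0.007, 0.006, 0.010),
)


def generate_hierarchy(
    n_states: int, counties_per_state: int | tuple[int, int], seed: int
) -> GeoHierarchy:
    """Reproducible synthetic state/county hierarchy.

    ``counties_per_state`` is either a constant or an inclusive (lo, hi)
    range sampled uniformly per state.
    """
    if n_states < 1:
        raise ValueError("need at least one state")
    rng = np.random.default_rng(seed)
    states = tuple(f"S{k + 1:02d}" for k in range(n_states))
    cbs: dict[str, tuple[str, ...]] = {}
    fips: dict[tuple[str, str], str] = {}
    for k, s in enumerate(states):
        if isinstance(counties_per_state, tuple):
            lo, hi = counties_per_state
            m = int(rng.integers(lo, hi + 1))
        else:
            m = int(counties_per_state)
        counties = tuple(f"C{j + 1:03d}" for j in range(m))
        cbs[s] = counties
        for j, c in enumerate(counties):
            fips[(s, c)] = f"{k + 1:02d}{(j + 1) * 2 - 1:03d}"
    return GeoHierarchy(states=states, counties_by_state=cbs, fips=fips)


def _draw_effects(rng, n: int, cov: np.ndarray) -> np.ndarray:
    """(n, q) Gaussian effects with the given covariance (PSD-safe)."""
    q = cov.shape[0]
    w, V = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    root = V * np.sqrt(w)
    return rng.standard_normal((n, q)) @ root.T


def _draw_populations(rng, hierarchy: GeoHierarchy, pop_range) -> np.ndarray:
    lo, hi = np.log(pop_range[0]), np.log(pop_range[1])
    return np.exp(rng.uniform(lo, hi, size=hierarchy.n_counties)).round().clip(min=20)


def _county_state_index(hierarchy: GeoHierarchy) -> np.ndarray:
    sidx = hierarchy.state_index()
    return np.array([sidx[s] for s, _ in hierarchy.county_keys])


def simulate_mortality_panel(
    params: GeneratorParams,
    times: tuple[int, ...] | None = (-3, -2, -1, 0),
    ages: tuple[int, ...] | None = None,
    seed: int = 0,
    hierarchy: GeoHierarchy | None = None,
    populations: np.ndarray | None = None,
):
    """Simulate Poisson mortality counts from the log-linear mixed model.

    In longitudinal mode (``times``) the log rate is
    ``alpha + a_k + a_jk + (beta + b_k + b_jk) * t`` with correlated
    (intercept, slope) pairs at each level; truth is the county rate at
    t = 0. In joint-age mode (``ages`` = 1..9) the linear predictor carries
    a shared intercept plus an independent random slope per non-reference
    age group, and truth is the per-age rate matrix.

    Returns ``(panel, truth)`` where ``truth`` is a DataFrame of latent
    rates keyed by county (and age, in age mode).
    """
    rng = np.random.default_rng(seed)
    if hierarchy is None:
        hierarchy = generate_hierarchy(params.n_states, params.counties_per_state, seed)
    C = hierarchy.n_counties
    keys = hierarchy.county_keys
    cs = _county_state_index(hierarchy)
    if populations is None:
        populations = _draw_populations(rng, hierarchy, params.pop_range)
    populations = np.asarray(populations, dtype=float)

    if (times is None) == (ages is None):
        raise ValueError("specify exactly one of times= or ages=")

    rows = []
    if times is not None:
        cov_s = params.level_cov("state")
        cov_c = params.level_cov("county")
        es = _draw_effects(rng, hierarchy.n_states, cov_s)
        ec = _draw_effects(rng, C, cov_c)
        beta = 0.0 if params.beta is None else float(np.asarray(params.beta).reshape(()))
        has_slope = cov_s.shape[0] == 2
        for t in times:
            eta = params.alpha + es[cs, 0] + ec[:, 0]
            if has_slope:
                eta = eta + (beta + es[cs, 1] + ec[:, 1]) * t
            else:
                eta = eta + beta * t
            rate = np.exp(eta)
            y = rng.poisson(rate * populations)
            for i, (s, c) in enumerate(keys):
                rows.append((s, c, hierarchy.fips.get((s, c), ""), t, y[i], populations[i]))
        eta0 = params.alpha + es[cs, 0] + ec[:, 0]
        truth = pd.DataFrame(
            {"state": [k[0] for k in keys], "county": [k[1] for k in keys],
             "rate": np.exp(eta0)}
        )
    else:
        ages = tuple(ages)
        if tuple(sorted(ages)) != tuple(range(1, 10)):
            raise ValueError("age mode expects the nine groups 1..9")
        beta = np.concatenate([[0.0], np.asarray(params.beta, float)])  # reference first
        tau_s = np.asarray(params.tau2_state, float)
        tau_c = np.asarray(params.tau2_county, float)
        if tau_s.shape != (8,) or tau_c.shape != (8,):
            raise ValueError("age mode needs 8 slope variances per level")
        a_s = rng.normal(0.0, np.sqrt(params.sigma2_state), hierarchy.n_states)
        a_c = rng.normal(0.0, np.sqrt(params.sigma2_county), C)
        b_s = rng.normal(0.0, np.sqrt(tau_s), size=(hierarchy.n_states, 8))
        b_c = rng.normal(0.0, np.sqrt(tau_c), size=(C, 8))
        pops_age = np.outer(populations, NATIONAL_AGE_SHARES).round().clip(min=1)
        truth_rows = []
        for a in range(1, 10):
            eta = params.alpha + a_s[cs] + a_c + beta[a - 1]
            if a >= 2:
                eta = eta + b_s[cs, a - 2] + b_c[:, a - 2]
            rate = np.exp(eta)
            n_a = pops_age[:, a - 1]
            y = rng.poisson(rate * n_a)
            for i, (s, c) in enumerate(keys):
                rows.append((s, c, hierarchy.fips.get((s, c), ""), a, y[i], n_a[i]))
                truth_rows.append((s, c, a, rate[i]))
        truth = pd.DataFrame(truth_rows, columns=["state", "county", "age", "rate"])

    df = pd.DataFrame(rows, columns=["state", "county", "fips", "t_or_age", "y", "n"])
    panel = GeoPanel(hierarchy, df, "counts", measure_name="mortality").sorted_copy()
    return panel, truth


def simulate_survey_means(
    params: GeneratorParams,
    seed: int = 0,
    hierarchy: GeoHierarchy | None = None,
    se_range: tuple[float, float] = (0.02, 0.3),
    n_resp_range: tuple[int, int] = (50, 3000),
):
    """Simulate a bivariate survey-mean panel (e.g. poor physical/mental days).

    Latent log means follow ``alpha + a_k + a_jk + (beta + b_k + b_jk) * i``
    for measures i = 0, 1 with correlated (intercept, contrast) effects;
    observed log means add Normal(0, s^2) sampling noise with per-cell
    log-scale SE ``s`` drawn log-uniformly over ``se_range``. The panel
    reports natural-scale means/SEs; truth holds the latent natural means.
    """
    rng = np.random.default_rng(seed)
    if hierarchy is None:
        hierarchy = generate_hierarchy(params.n_states, params.counties_per_state, seed)
    C = hierarchy.n_counties
    keys = hierarchy.county_keys
    cs = _county_state_index(hierarchy)
    es = _draw_effects(rng, hierarchy.n_states, params.level_cov("state"))
    ec = _draw_effects(rng, C, params.level_cov("county"))
    beta = 0.0 if params.beta is None else float(np.asarray(params.beta).reshape(()))
    has_slope = es.shape[1] == 2

    rows, truth_rows = [], []
    for i in (0, 1):
        eta = params.alpha + es[cs, 0] + ec[:, 0]
        if has_slope:
            eta = eta + (beta + es[cs, 1] + ec[:, 1]) * i
        else:
            eta = eta + beta * i
        s = np.exp(rng.uniform(np.log(se_range[0]), np.log(se_range[1]), C))
        obs_log = eta + rng.normal(0.0, s)
        m = np.exp(obs_log)
        n_resp = np.exp(
            rng.uniform(np.log(n_resp_range[0]), np.log(n_resp_range[1]), C)
        ).round().astype(int)
        for j, (st, c) in enumerate(keys):
            rows.append(
                (st, c, hierarchy.fips.get((st, c), ""), i, m[j], s[j] * m[j], n_resp[j])
            )
            truth_rows.append((st, c, i, np.exp(eta[j])))
    df = pd.DataFrame(
        rows, columns=["state", "county", "fips", "measure", "mean", "se", "n_resp"]
    )
    truth = pd.DataFrame(truth_rows, columns=["state", "county", "measure", "mean"])
    panel = GeoPanel(hierarchy, df, "survey_mean", measure_name="health_days").sorted_copy()
    return panel, truth


def simulate_binomial_pair(
    params: GeneratorParams,
    seed: int = 0,
    hierarchy: GeoHierarchy | None = None,
    denominators: np.ndarray | None = None,
    n_range: tuple[float, float] = (60, 2e4),
):
    """Simulate a bivariate binomial panel on the logit scale.

    ``logit(pi) = alpha + a_k + a_jk + (beta + b_k + b_jk) * i``; counts
    ``y ~ Binomial(n, pi)`` with per-cell denominators drawn log-uniformly
    over ``n_range`` unless supplied (shape (C, 2)). Truth holds the latent
    proportions.
    """
    rng = np.random.default_rng(seed)
    if hierarchy is None:
        hierarchy = generate_hierarchy(params.n_states, params.counties_per_state, seed)
    C = hierarchy.n_counties
    keys = hierarchy.county_keys
    cs = _county_state_index(hierarchy)
    es = _draw_effects(rng, hierarchy.n_states, params.level_cov("state"))
    ec = _draw_effects(rng, C, params.level_cov("county"))
    beta = 0.0 if params.beta is None else float(np.asarray(params.beta).reshape(()))
    has_slope = es.shape[1] == 2
    if denominators is None:
        denominators = np.exp(
            rng.uniform(np.log(n_range[0]), np.log(n_range[1]), size=(C, 2))
        ).round().astype(int)
    denominators = np.asarray(denominators)

    rows, truth_rows = [], []
    for i in (0, 1):
        eta = params.alpha + es[cs, 0] + ec[:, 0]
        if has_slope:
            eta = eta + (beta + es[cs, 1] + ec[:, 1]) * i
        else:
            eta = eta + beta * i
        pi = 1.0 / (1.0 + np.exp(-eta))
        n = denominators[:, i]
        y = rng.binomial(n, pi)
        se = np.sqrt(np.clip(pi * (1 - pi), 1e-12, None) / n)
        for j, (st, c) in enumerate(keys):
            rows.append(
                (st, c, hierarchy.fips.get((st, c), ""), i,
                 y[j] / n[j], se[j], y[j], n[j])
            )
            truth_rows.append((st, c, i, pi[j]))
    df = pd.DataFrame(
        rows, columns=["state", "county", "fips", "measure", "p", "se", "y", "n"]
    )
    truth = pd.DataFrame(truth_rows, columns=["state", "county", "measure", "p"])
    panel = GeoPanel(hierarchy, df, "proportion", measure_name="prevalence_pair").sorted_copy()
    return panel, truth


def inject_missingness(
    panel: GeoPanel, rate: float | None = None, rule: str | None = None, seed: int = 0
) -> GeoPanel:
    """Flag records as suppressed, by Bernoulli(rate) or by the named rule.

    ``rule`` may be ``"vital"`` (small-count suppression) or ``"brfss"``
    (respondent-count / CI-width censoring); ``rate`` draws independent
    suppression indicators per record.
    """
    if (rate is None) == (rule is None):
        raise ValueError("specify exactly one of rate= or rule=")
    if rule == "vital":
        return apply_vital_suppression(panel)
    if rule == "brfss":
        return apply_brfss_censoring(panel)
    if rule is not None:
        raise ValueError(f"unknown rule {rule!r}")
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    df = panel.data.copy()
    df["suppressed"] = df["suppressed"] | (rng.random(len(df)) < rate)
    return GeoPanel(panel.hierarchy, df, panel.schema, panel.measure_name)
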