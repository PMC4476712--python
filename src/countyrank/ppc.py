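"""Posterior predictive model checking.

Replicate datasets are generated from the posterior measure draws with the
same sampling model and the observed denominators (population counts,
binomial trials, known sampling variances), and compared to the observed
county-level outcome vector through two distributional summaries: the
inter-quartile range and the (adjusted Fisher-Pearson) skewness. Mean
values replicate even under a mis-specified model, so dispersion and shape
carry the diagnostic signal. A two-sided posterior predictive p-value below
0.05 flags poor fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .draws import PosteriorDraws
from .panel import GeoPanel

__all__ = [
    "PPCResult",
    "replicate_data",
    "observed_outcomes",
    "sample_iqr",
    "sample_skew",
    "ppp_value",
    "ppc_check",
    "run_ppc",
    "run_panel_ppc",
]


@dataclass
class PPCResult:
    statistic: str  # "iqr" or "skew"
    observed: float
    replicates: np.ndarray
    p_value: float
    poor_fit: bool  # p < 0.05

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def observed_outcomes(panel: GeoPanel, measure: int | None = None,
                      index: int | None = None) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Observed county outcome vector and its sampling auxiliaries.

    Returns ``(obs, aux, roster)`` where ``obs`` is the outcome on the scale
    the checks compare (event rate y/n, proportion, or observed log mean)
    and ``aux`` the per-county denominator (n) or known log-scale sampling
    variance, aligned on the active-record roster.
    """
    df = panel.active()
    if measure is not None and "measure" in df.columns:
        df = df.loc[df["measure"].astype(int) == measure]
    if index is not None and "t_or_age" in df.columns:
        df = df.loc[df["t_or_age"].astype(int) == index]
    if len(df) == 0:
        raise ValueError("no active records for the requested slice")
    df = df.sort_values(["state", "county"], kind="mergesort")
    roster = tuple(zip(df["state"], df["county"]))
    if panel.schema == "counts":
        n = df["n"].to_numpy(float)
        obs = df["y"].to_numpy(float) / n
        aux = n
    elif panel.schema == "proportion":
        from .panel import effective_sample_size

        ys, ns = [], []
        for _, r in df.iterrows():
            if pd.notna(r.get("y")) and pd.notna(r.get("n")):
                ys.append(float(r["y"]))
                ns.append(float(r["n"]))
            else:
                n_eff, y_eff = effective_sample_size(float(r["p"]), float(r["se"]))
                ys.append(float(y_eff))
                ns.append(float(n_eff))
        obs = np.array(ys) / np.array(ns)
        aux = np.array(ns)
    else:  # survey_mean: compare observed log means with known sampling variance
        m = df["mean"].to_numpy(float)
        se = df["se"].to_numpy(float)
        obs = np.log(m)
        aux = (se / m) ** 2
    return obs, aux, roster


def replicate_data(
    draws: PosteriorDraws, aux: np.ndarray, family: str, seed: int,
    columns: np.ndarray | None = None,
) -> np.ndarray:
    """(D, C) replicate outcome vectors from the posterior measure draws.

    Per draw d and county: ``Poisson(rho_d * n) / n`` rates,
    ``Binomial(n, pi_d) / n`` proportions, or ``Normal(log mu_d, s^2)``
    observed log means, using each county's actual denominator / variance.
    ``columns`` selects (and orders) draw columns when the panel roster is a
    subset of the fitted roster.
    """
    rng = np.random.default_rng(seed)
    values = draws.values if columns is None else draws.values[:, columns]
    aux = np.asarray(aux, float)
    if values.shape[1] != aux.shape[0]:
        raise ValueError("draw roster does not match the panel roster")
    if family == "poisson":
        return rng.poisson(values * aux) / aux
    if family == "binomial":
        n = aux.astype(np.int64)
        return rng.binomial(n, np.clip(values, 0.0, 1.0)) / n
    if family == "normal_known_variance":
        return rng.normal(np.log(values), np.sqrt(aux))
    raise ValueError(f"unknown family {family!r}")


def sample_iqr(values) -> float:
    """Inter-quartile range with linear-interpolation quantiles."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise ValueError("IQR needs at least 4 finite values")
    q1, q3 = np.percentile(values, [25.0, 75.0])
    return float(q3 - q1)


def sample_skew(values) -> float:
    """Adjusted Fisher-Pearson skewness g1 * sqrt(n(n-1)) / (n-2)."""
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if values.size < 3:
        raise ValueError("skewness needs at least 3 finite values")
    return float(stats.skew(values, bias=False))


_STATS = {"iqr": sample_iqr, "skew": sample_skew}


def ppp_value(observed: float, replicates: np.ndarray) -> float:
    """Two-sided posterior predictive p-value.

    ``p = 2 * min(Pr(T_rep >= T_obs), Pr(T_rep <= T_obs))`` with ties counted
    in both tails (empirical fractions), capped at 1; both tails flag misfit
    (a model can over- as well as under-disperse).
    """
    replicates = np.asarray(replicates, float)
    if replicates.size == 0:
        raise ValueError("no replicates")
    upper = float(np.mean(replicates >= observed))
    lower = float(np.mean(replicates <= observed))
    return min(1.0, 2.0 * min(upper, lower))


def ppc_check(observed_vec: np.ndarray, replicate_mat: np.ndarray,
              statistic: str) -> PPCResult:
    """Compare one distributional statistic of the observed county vector
    against its posterior predictive distribution."""
    fn = _STATS[statistic]
    obs_stat = fn(observed_vec)
    reps = np.array([fn(row) for row in np.asarray(replicate_mat, float)])
    p = ppp_value(obs_stat, reps)
    return PPCResult(
        statistic=statistic, observed=obs_stat, replicates=reps,
        p_value=p, poor_fit=p < 0.05,
    )


def run_panel_ppc(
    fit, panel: GeoPanel, n_draws: int, seed: int,
    statistics: tuple[str, ...] = ("iqr", "skew"),
) -> list[PPCResult]:
    """Replicate the entire counts panel and check its dispersion and shape.

    For a longitudinal fit every county-by-time cell is replicated from the
    same joint posterior sample (the linear predictor is re-assembled at each
    time point), so the observed vector is the full set of cell rates y/n.
    This is the strictest dispersion check available: within-county noise
    that the model's two latent degrees of freedom per county cannot explain
    shows up directly. For a cross-sectional fit it reduces to the single
    reference-period check.
    """
    from .draws import sample_effect_draws, _assemble

    if panel.schema != "counts":
        raise ValueError("panel replication needs a counts panel")
    if fit.spec.design not in ("cross_sectional", "longitudinal"):
        raise ValueError("panel replication covers cross-sectional/longitudinal fits")
    df = panel.active().sort_values(["t_or_age", "state", "county"], kind="mergesort")
    cidx = {k: i for i, k in enumerate(fit.roster)}
    cols = np.array([cidx[(s, c)] for s, c in zip(df["state"], df["county"])])
    n = df["n"].to_numpy(float)
    obs = df["y"].to_numpy(float) / n
    tvals = df["t_or_age"].to_numpy(int)

    beta_d, us_d, uc_d = sample_effect_draws(fit, n_draws, seed)
    rates = np.empty((n_draws, len(df)))
    for t in np.unique(tvals):
        x_ref = (np.array([1.0, float(t)]) if fit.spec.design == "longitudinal"
                 else np.ones(1))
        block = _assemble(fit, beta_d, us_d, uc_d, x_ref)
        sel = tvals == t
        rates[:, sel] = block[:, cols[sel]]
    rng = np.random.default_rng(seed + 1)
    reps = rng.poisson(rates * n) / n
    return [ppc_check(obs, reps, s) for s in statistics]


def run_ppc(
    draws: PosteriorDraws, panel: GeoPanel, family: str, seed: int,
    measure: int | None = None, index: int | None = None,
    statistics: tuple[str, ...] = ("iqr", "skew"),
) -> list[PPCResult]:
    """Full check for one measure: replicate data, then IQR and skew p-values."""
    obs, aux, roster = observed_outcomes(panel, measure=measure, index=index)
    cidx = {k: i for i, k in enumerate(draws.counties)}
    try:
        columns = np.array([cidx[k] for k in roster])
    except KeyError as e:
        raise ValueError(f"panel county {e.args[0]!r} missing from draw roster")
    reps = replicate_data(draws, aux, family, seed, columns=columns)
    return [ppc_check(obs, reps, s) for s in statistics]
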