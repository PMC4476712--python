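"""Posterior simulation of county-level measures and the YPLL-75 composite.

Draws follow the empirical-Bayes recipe: fixed effects are sampled from a
multivariate normal at their estimate and covariance, and every state and
county random-effect block is sampled independently from its conditional
(EB) normal distribution. The linear predictor is assembled at the
reference point of the design (t = 0; each age group; each measure) and
inverse-linked to the natural scale, giving a D x C matrix of rates, mean
days, or proportions per measure.

The YPLL-75 composite weights each age-specific death rate by the years of
potential life lost before 75 (75 minus the age-interval midpoint) and the
county's age-group population share, expressed per 100,000 population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .fit import FitResult
from .panel import GeoPanel
from .simulate import AGE_GROUP_LABELS

__all__ = ["PosteriorDraws", "AgeSchedule", "draw_posterior", "ypll75", "YPLL_WEIGHTS"]

#: years lost per death by age group: 75 minus the interval midpoint for
#: intervals [0,1), [1,5), [5,15), ..., [65,75)
YPLL_WEIGHTS = np.array([74.5, 72.0, 65.0, 55.0, 45.0, 35.0, 25.0, 15.0, 5.0])


@dataclass
class PosteriorDraws:
    """D x C matrix of natural-scale measure draws, columns in roster order."""

    values: np.ndarray
    counties: tuple[tuple[str, str], ...]
    measure_name: str
    draw_seed: int | None = None
    family: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2:
            raise ValueError("draw values must be a (draws, counties) matrix")
        if self.values.shape[1] != len(self.counties):
            raise ValueError("column count must match the county roster")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("draws contain non-finite values")

    @property
    def n_draws(self) -> int:
        return self.values.shape[0]

    @property
    def n_counties(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{s}:{c}" for s, c in self.counties]
        return pd.DataFrame(self.values, columns=cols)


@dataclass
class AgeSchedule:
    """Age-group populations and YPLL weights per county.

    ``populations`` has one row per county (roster order) and nine columns;
    weights default to 75 minus the age-interval midpoint and must be
    positive and decreasing in age.
    """

    counties: tuple[tuple[str, str], ...]
    populations: np.ndarray
    weights: np.ndarray = field(default_factory=lambda: YPLL_WEIGHTS.copy())
    labels: tuple[str, ...] = AGE_GROUP_LABELS

    def __post_init__(self):
        self.populations = np.asarray(self.populations, float)
        self.weights = np.asarray(self.weights, float)
        if self.populations.shape != (len(self.counties), 9):
            raise ValueError("populations must be (n_counties, 9)")
        if self.weights.shape != (9,):
            raise ValueError("nine YPLL weights required")
        if np.any(self.weights <= 0) or np.any(np.diff(self.weights) >= 0):
            raise ValueError("weights must be positive and decreasing in age")

    @staticmethod
    def from_panel(panel: GeoPanel, t: int | None = None) -> "AgeSchedule":
        """Build the schedule from a counts panel holding nine age rows per county."""
        if panel.schema != "counts":
            raise ValueError("age schedule needs a counts panel")
        df = panel.data
        if t is not None and "t_or_age" in df.columns:
            pass  # age panels index by age; t is accepted for symmetry
        roster = tuple(panel.hierarchy.county_keys)
        cidx = {k: i for i, k in enumerate(roster)}
        pops = np.zeros((len(roster), 9))
        for _, r in df.iterrows():
            a = int(r["t_or_age"])
            if not 1 <= a <= 9:
                raise ValueError("age panel must index age groups 1..9")
            pops[cidx[(r["state"], r["county"])], a - 1] = float(r["n"])
        if np.any(pops.sum(axis=1) <= 0):
            raise ValueError("every county needs age-group populations")
        return AgeSchedule(counties=roster, populations=pops)


def _batch_mvn(rng, means, covs, n_draws):
    """(D, B, q) draws from B independent MVNs given means (B,q), covs (B,q,q)."""
    B, q = means.shape
    w, V = np.linalg.eigh(covs)
    root = V * np.sqrt(np.clip(w, 0.0, None))[:, None, :]
    eps = rng.standard_normal((n_draws, B, q))
    return means[None] + np.einsum("bqr,dbr->dbq", root, eps)


def sample_effect_draws(fit: FitResult, n_draws: int, seed: int,
                        zero_covariance: bool = False):
    """Joint posterior samples of fixed effects and every random-effect block.

    Fixed effects come from MVN(estimate, covariance); each state and county
    block independently from MVN(EB conditional mean, EB conditional
    covariance). Returns ``(beta, state_blocks, county_blocks)`` with shapes
    (D, p), (D, K, q), (D, C, q). ``zero_covariance`` collapses every
    distribution onto its mean.
    """
    if n_draws < 2:
        raise ValueError("need at least 2 draws")
    if zero_covariance:
        return (
            np.tile(fit.fixed, (n_draws, 1)),
            np.tile(fit.eb_mean_state, (n_draws, 1, 1)),
            np.tile(fit.eb_mean_county, (n_draws, 1, 1)),
        )
    rng = np.random.default_rng(seed)
    w = np.linalg.eigvalsh(fit.fixed_cov)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError("fixed-effect covariance is not positive semi-definite")
    L = np.linalg.cholesky(fit.fixed_cov + 1e-12 * np.eye(len(fit.fixed)))
    beta_d = fit.fixed[None] + rng.standard_normal((n_draws, len(fit.fixed))) @ L.T
    us_d = _batch_mvn(rng, fit.eb_mean_state, fit.eb_cov_state, n_draws)
    uc_d = _batch_mvn(rng, fit.eb_mean_county, fit.eb_cov_county, n_draws)
    return beta_d, us_d, uc_d


def _assemble(fit: FitResult, beta_d, us_d, uc_d, x_ref):
    inv_link = (
        np.exp if fit.spec.family in ("poisson", "normal_known_variance")
        else special.expit
    )
    cs = fit.county_state
    eta = (
        (beta_d @ x_ref)[:, None]
        + np.einsum("dkq,q->dk", us_d, x_ref)[:, cs]
        + np.einsum("dcq,q->dc", uc_d, x_ref)
    )
    return inv_link(eta)


def draw_posterior(
    fit: FitResult, n_draws: int, seed: int, zero_covariance: bool = False,
    at_time: float | None = None,
) -> dict[str, PosteriorDraws]:
    """Simulate the approximate joint posterior and return natural-scale draws.

    Returns one :class:`PosteriorDraws` per output level: a single entry for
    cross-sectional/longitudinal fits, one per age group for joint-age fits,
    and one per measure for joint-bivariate fits.

    ``at_time`` moves the longitudinal reference point away from the default
    t = 0 (e.g. -3..-1 when replicating a full panel); only meaningful for
    the longitudinal design. ``zero_covariance`` collapses every sampling
    distribution onto its mean (useful for degenerate checks: each draw is
    then the EB point prediction).
    """
    beta_d, us_d, uc_d = sample_effect_draws(fit, n_draws, seed, zero_covariance)
    if at_time is not None and fit.spec.design != "longitudinal":
        raise ValueError("at_time applies only to longitudinal fits")
    out: dict[str, PosteriorDraws] = {}
    for key, x_ref in fit.reference_rows().items():
        if at_time is not None:
            x_ref = np.array([1.0, float(at_time)])
        out[key] = PosteriorDraws(
            values=_assemble(fit, beta_d, us_d, uc_d, x_ref),
            counties=fit.roster,
            measure_name=key,
            draw_seed=seed,
            family=fit.spec.family,
        )
    return out


def ypll75(
    age_draws: dict[str, PosteriorDraws] | list[PosteriorDraws],
    schedule: AgeSchedule,
) -> PosteriorDraws:
    """Combine nine age-specific rate draws into YPLL-75 per 100,000.

    For each draw and county: ``1e5 * sum_a rho_a * n_a * w_a / sum_a n_a``
    where ``rho_a`` is the age-specific death rate draw, ``n_a`` the county's
    age-group population and ``w_a`` the years lost per death.
    """
    if isinstance(age_draws, dict):
        keys = sorted(age_draws, key=lambda k: int(k.rsplit("_", 1)[-1]))
        draws = [age_draws[k] for k in keys]
    else:
        draws = list(age_draws)
    if len(draws) != 9:
        raise ValueError("YPLL-75 needs nine age-group draw sets")
    roster = draws[0].counties
    for d in draws:
        if d.counties != roster:
            raise ValueError("age-group draws have mismatched county rosters")
    if schedule.counties != roster:
        raise ValueError("age schedule roster does not match the draws")
    total = schedule.populations.sum(axis=1)
    acc = np.zeros_like(draws[0].values)
    for a, d in enumerate(draws):
        acc += d.values * schedule.populations[:, a] * schedule.weights[a]
    values = 1e5 * acc / total
    return PosteriorDraws(
        values=values,
        counties=roster,
        measure_name="ypll75",
        draw_seed=draws[0].draw_seed,
        family="poisson",
    )
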