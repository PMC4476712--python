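"""National rank inference from posterior measure draws.

Within each posterior draw, counties are ranked on the measure (rank 1 =
healthiest, i.e. lowest value when higher is worse). Point ranks minimize
squared error loss on the rank scale: they are the ranks of the posterior
mean ranks. National quartiles are assigned from the point ranks
(quartile 1 healthiest), quartile-membership probabilities are the
fractions of draws in which a county's within-draw rank lands in each
quartile's rank interval, and each county gets a certainty class from the
probability of its assigned quartile: low (< 0.50), medium (0.50-0.75),
high (>= 0.75).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .draws import PosteriorDraws

__all__ = [
    "RankSummary",
    "rank_draws",
    "point_ranks",
    "assign_quartiles",
    "quartile_probabilities",
    "certainty_class",
    "summarize_ranks",
    "precision_report",
]


def _values_and_roster(draws):
    if isinstance(draws, PosteriorDraws):
        return draws.values, draws.counties
    return np.asarray(draws, float), None


def _rank_rows(values: np.ndarray) -> np.ndarray:
    """Rank each row ascending; ties broken deterministically by column order.

    Measure draws are continuous so ties have probability ~0; when inputs are
    duplicated the earlier county (roster order) takes the smaller rank,
    keeping every row an exact permutation of 1..C.
    """
    D, C = values.shape
    order = np.argsort(values, axis=1, kind="stable")
    ranks = np.empty((D, C), dtype=np.int64)
    rows = np.arange(D)[:, None]
    ranks[rows, order] = np.arange(1, C + 1)
    return ranks


def rank_draws(draws, direction: str = "higher_is_worse") -> np.ndarray:
    """(D, C) within-draw ranks; rank 1 = healthiest county in that draw."""
    values, _ = _values_and_roster(draws)
    if values.shape[1] < 2:
        raise ValueError("ranking needs at least two counties")
    if not np.all(np.isfinite(values)):
        raise ValueError("draws contain non-finite values")
    if direction == "higher_is_worse":
        return _rank_rows(values)
    if direction == "higher_is_better":
        return _rank_rows(-values)
    raise ValueError(f"unknown direction {direction!r}")


def point_ranks(rank_matrix: np.ndarray) -> np.ndarray:
    """Squared-error-loss point ranks: rank the posterior mean ranks."""
    rank_matrix = np.asarray(rank_matrix)
    mean_ranks = rank_matrix.mean(axis=0)
    return _rank_rows(mean_ranks[None, :])[0]


def quartile_cutoffs(C: int) -> np.ndarray:
    """Upper rank bound of each quartile: ceil(C*q/4) for q = 1..4."""
    return np.ceil(C * np.arange(1, 5) / 4.0).astype(np.int64)


def assign_quartiles(ranks: np.ndarray, C: int | None = None) -> np.ndarray:
    """Map ranks to national quartiles 1..4 (1 = healthiest).

    Rank r belongs to the smallest q with r <= ceil(C*q/4); quartile sizes
    never differ by more than one county.
    """
    ranks = np.asarray(ranks)
    if C is None:
        C = int(ranks.max())
    cut = quartile_cutoffs(C)
    return (np.searchsorted(cut, ranks, side="left") + 1).astype(np.int64)


def quartile_probabilities(rank_matrix: np.ndarray, C: int | None = None) -> np.ndarray:
    """(C, 4) fractions of draws in which each county lands in each quartile."""
    rank_matrix = np.asarray(rank_matrix)
    D, n = rank_matrix.shape
    if C is None:
        C = n
    qm = assign_quartiles(rank_matrix, C)
    probs = np.stack([(qm == q).mean(axis=0) for q in (1, 2, 3, 4)], axis=1)
    return probs


def certainty_class(prob_assigned):
    """low (< 0.50) / medium (0.50-0.75) / high (>= 0.75) certainty labels."""
    scalar = np.ndim(prob_assigned) == 0
    p = np.atleast_1d(np.asarray(prob_assigned, float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    out = np.where(p >= 0.75, "high", np.where(p >= 0.50, "medium", "low"))
    return str(out[0]) if scalar else out


@dataclass
class RankSummary:
    """Per-county rank point estimates, quartiles, and certainty."""

    table: pd.DataFrame  # county, state, mean_rank, point_rank, quartile,
    #                      p_q1..p_q4, p_assigned, certainty
    n_counties: int
    n_draws: int
    measure_name: str = ""

    def high_certainty_share(self) -> float:
        return float((self.table["certainty"] == "high").mean())


def summarize_ranks(
    draws: PosteriorDraws, direction: str = "higher_is_worse"
) -> RankSummary:
    """Full rank inference for one measure's posterior draws."""
    rm = rank_draws(draws, direction)
    D, C = rm.shape
    mean_rank = rm.mean(axis=0)
    pr = point_ranks(rm)
    quart = assign_quartiles(pr, C)
    probs = quartile_probabilities(rm, C)
    p_assigned = probs[np.arange(C), quart - 1]
    values, roster = _values_and_roster(draws)
    if roster is None:
        roster = tuple(("", str(i)) for i in range(C))
    fips = [""] * C
    table = pd.DataFrame(
        {
            "state": [s for s, _ in roster],
            "county": [c for _, c in roster],
            "fips": fips,
            "mean_rank": mean_rank,
            "point_rank": pr,
            "quartile": quart,
            "p_q1": probs[:, 0],
            "p_q2": probs[:, 1],
            "p_q3": probs[:, 2],
            "p_q4": probs[:, 3],
            "p_assigned": p_assigned,
            "certainty": certainty_class(p_assigned),
        }
    )
    return RankSummary(
        table=table,
        n_counties=C,
        n_draws=D,
        measure_name=getattr(draws, "measure_name", ""),
    )


def precision_report(summaries: dict[str, RankSummary]) -> pd.DataFrame:
    """Percent and number of high-certainty counties by quartile and in total.

    One row per model-measure label; columns q1..q4 and total, each as a
    percent of all ranked counties, with matching county counts.
    """
    if not summaries:
        raise ValueError("need at least one rank summary")
    rows = []
    for label, summ in summaries.items():
        t = summ.table
        high = t["certainty"] == "high"
        C = summ.n_counties
        row = {"model": label, "n_counties": C}
        total_n = 0
        for q in (1, 2, 3, 4):
            n = int((high & (t["quartile"] == q)).sum())
            row[f"q{q}_pct"] = 100.0 * n / C
            row[f"q{q}_n"] = n
            total_n += n
        row["total_pct"] = 100.0 * total_n / C
        row["total_n"] = total_n
        rows.append(row)
    return pd.DataFrame(rows)
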