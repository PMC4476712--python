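"""Independent oracles used by the test suite.

Each oracle reaches the quantity under test by a different route than the
package (dense covariance algebra, exact numerical integration, exhaustive
enumeration, or per-item brute-force summation), so agreement is evidence
of correctness rather than self-consistency.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize, special
from scipy.optimize import minimize_scalar

# ---------------------------------------------------------------------------
# exact two-level Gaussian ML via dense marginal covariance


def gaussian_ml_oracle(z, s2, state_labels):
    """Exact ML for z_jk ~ N(b0 + e_k + e_jk, s2_jk) via the dense marginal
    covariance V = diag(s2) + sc2*I + ss2*(state blocks), profiling b0 by GLS
    and optimizing the two log-variances (coarse grid + Nelder-Mead).

    Returns (b0, ss2, sc2, loglik).
    """
    z = np.asarray(z, float)
    s2 = np.asarray(s2, float)
    labels = np.asarray(state_labels)
    svals = sorted(set(labels.tolist()))
    n = len(z)
    one = np.ones(n)

    def negll_b0(theta):
        ss, sc = np.exp(theta)
        V = np.diag(s2 + sc)
        for s in svals:
            idx = np.flatnonzero(labels == s)
            V[np.ix_(idx, idx)] += ss
        Vi = np.linalg.inv(V)
        b0 = (one @ Vi @ z) / (one @ Vi @ one)
        r = z - b0
        _, ld = np.linalg.slogdet(V)
        return 0.5 * (r @ Vi @ r + ld + n * np.log(2 * np.pi)), b0

    best = None
    for ls in np.linspace(-7, 0, 8):
        for lc in np.linspace(-7, 0, 8):
            v, _ = negll_b0([ls, lc])
            if best is None or v < best[0]:
                best = (v, [ls, lc])
    res = optimize.minimize(
        lambda th: negll_b0(th)[0],
        best[1],
        method="Nelder-Mead",
        options=dict(xatol=1e-13, fatol=1e-15, maxiter=6000, maxfev=12000),
    )
    nll, b0 = negll_b0(res.x)
    return b0, float(np.exp(res.x[0])), float(np.exp(res.x[1])), -nll


def gaussian_eb_oracle(z, s2, state_labels, b0, ss2, sc2):
    """Closed-form (precision-weighted GLS) conditional means of all random
    effects for the known-variance Gaussian model: u | z is Gaussian with mean
    (Z'R^-1 Z + G^-1)^-1 Z'R^-1 (z - b0). Returns (state_means, county_means)
    with states sorted and counties in input order."""
    z = np.asarray(z, float)
    labels = np.asarray(state_labels)
    svals = sorted(set(labels.tolist()))
    n = len(z)
    K = len(svals)
    Zs = np.zeros((n, K))
    for k, s in enumerate(svals):
        Zs[labels == s, k] = 1.0
    Zc = np.eye(n)  # one observation per county
    Z = np.hstack([Zs, Zc])
    Ginv = np.diag(np.concatenate([np.full(K, 1.0 / ss2), np.full(n, 1.0 / sc2)]))
    Rinv = np.diag(1.0 / np.asarray(s2, float))
    mean = np.linalg.solve(Z.T @ Rinv @ Z + Ginv, Z.T @ Rinv @ (z - b0))
    return mean[:K], mean[K:]


# ---------------------------------------------------------------------------
# exact Poisson two-level ML via nested adaptive Gauss-Hermite quadrature

_GHX, _GHW = np.polynomial.hermite.hermgauss(40)


def _county_marginal(eta0, yj, nj, sc2):
    """log int N(u; 0, sc2) Poisson(y | n e^(eta0+u)) du, adaptive GH."""

    def logf(u):
        lam = nj * np.exp(eta0 + u)
        return (
            yj * np.log(lam) - lam - special.gammaln(yj + 1)
            - 0.5 * u * u / sc2 - 0.5 * np.log(2 * np.pi * sc2)
        )

    u = 0.0
    for _ in range(60):
        lam = nj * np.exp(eta0 + u)
        du = ((yj - lam) - u / sc2) / (lam + 1.0 / sc2)
        u += du
        if abs(du) < 1e-14:
            break
    h = 1.0 / np.sqrt(nj * np.exp(eta0 + u) + 1.0 / sc2)
    pts = u + np.sqrt(2.0) * h * _GHX
    vals = np.array([logf(p) for p in pts]) + _GHX**2
    m = vals.max()
    return m + np.log(np.sum(_GHW * np.exp(vals - m))) + np.log(np.sqrt(2.0) * h)


def _state_marginal(b0, ys, ns, ss2, sc2):
    def logint(a):
        return (
            sum(_county_marginal(b0 + a, yj, nj, sc2) for yj, nj in zip(ys, ns))
            - 0.5 * a * a / ss2 - 0.5 * np.log(2 * np.pi * ss2)
        )

    r = minimize_scalar(lambda a: -logint(a), bounds=(-4, 4), method="bounded",
                        options={"xatol": 1e-11})
    a0 = r.x
    d = 1e-4
    H = max(-(logint(a0 + d) - 2 * logint(a0) + logint(a0 - d)) / d**2, 1e-8)
    h = 1.0 / np.sqrt(H)
    pts = a0 + np.sqrt(2.0) * h * _GHX
    vals = np.array([logint(p) for p in pts]) + _GHX**2
    m = vals.max()
    return m + np.log(np.sum(_GHW * np.exp(vals - m))) + np.log(np.sqrt(2.0) * h)


def poisson_ml_quadrature_oracle(y, n, state_labels):
    """Exact (numerically integrated) ML for the two-level Poisson model on a
    small instance. Returns (b0, ss2, sc2, loglik)."""
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    labels = np.asarray(state_labels)
    svals = sorted(set(labels.tolist()))

    def negll(x):
        b0, ls, lc = x
        ss2, sc2 = np.exp(ls), np.exp(lc)
        tot = 0.0
        for s in svals:
            idx = labels == s
            tot += _state_marginal(b0, y[idx], n[idx], ss2, sc2)
        return -tot

    x0 = [np.log(y.sum() / n.sum()), np.log(0.04), np.log(0.05)]
    res = optimize.minimize(
        negll, x0, method="Nelder-Mead",
        options=dict(xatol=1e-10, fatol=1e-12, maxiter=4000, maxfev=8000),
    )
    return res.x[0], float(np.exp(res.x[1])), float(np.exp(res.x[2])), -res.fun


# ---------------------------------------------------------------------------
# ranking oracles


def rank_rows_bruteforce(values):
    """Per-row sort oracle: rank 1 = smallest, ties broken by column order."""
    values = np.asarray(values, float)
    out = np.zeros(values.shape, dtype=np.int64)
    for d, row in enumerate(values):
        order = sorted(range(len(row)), key=lambda c: (row[c], c))
        for r, c in enumerate(order, start=1):
            out[d, c] = r
    return out


def sel_optimal_permutation(rank_matrix):
    """Exhaustive squared-error-loss minimizer over all candidate rank vectors
    (permutations of 1..C); feasible for C <= 6."""
    rm = np.asarray(rank_matrix, float)
    C = rm.shape[1]
    best, best_loss = None, np.inf
    for perm in itertools.permutations(range(1, C + 1)):
        loss = float(((rm - np.array(perm)) ** 2).sum())
        if loss < best_loss - 1e-12:
            best, best_loss = np.array(perm), loss
    return best


def quartile_probs_bruteforce(rank_matrix, C):
    """Enumerate every draw and count quartile membership per county."""
    rm = np.asarray(rank_matrix)
    D, n = rm.shape
    cut = [int(np.ceil(C * q / 4.0)) for q in range(1, 5)]

    def quartile(r):
        for q, c in enumerate(cut, start=1):
            if r <= c:
                return q
        raise AssertionError

    probs = np.zeros((n, 4))
    for d in range(D):
        for c in range(n):
            probs[c, quartile(rm[d, c]) - 1] += 1
    return probs / D


# ---------------------------------------------------------------------------
# YPLL-75 brute-force oracle


def ypll_bruteforce(age_rate_draws, populations, weights):
    """Per-death weighted summation: for every draw and county, accumulate
    expected deaths in each age group times that group's years lost, then
    express per 100,000 total population. Pure Python loops."""
    D = age_rate_draws[0].shape[0]
    C = age_rate_draws[0].shape[1]
    out = np.zeros((D, C))
    for d in range(D):
        for c in range(C):
            years = 0.0
            pop = 0.0
            for a in range(9):
                deaths = age_rate_draws[a][d, c] * populations[c][a]
                years += deaths * weights[a]
                pop += populations[c][a]
            out[d, c] = 1e5 * years / pop
    return out
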