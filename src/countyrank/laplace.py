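"""Maximum-likelihood estimation of two-level nested GLMMs by Laplace
approximation.

The model: observations i carry a fixed design row ``x_i`` and a random
design row ``z_i``; each observation belongs to one county j nested in one
state k, and the linear predictor is

    eta_i = x_i' beta + z_i' u_k + z_i' u_jk

with state blocks ``u_k ~ N(0, Lambda_s)`` and county blocks
``u_jk ~ N(0, Lambda_c)``.  Families: Poisson (log link, offset), binomial
(logit link) and normal with known per-observation variance (for which the
"approximation" is exact).

Estimation profiles the random-effect modes out of the joint log-density
with a damped Newton solver that exploits the arrowhead sparsity of the
penalized Hessian (counties are conditionally independent given their
state), then maximizes the Laplace-approximate marginal likelihood over
(beta, log-SDs, atanh-correlations) with a quasi-Newton outer loop.
Empirical-Bayes conditional means and covariances of every block come from
the same arrowhead factorization at the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = ["CovStructure", "NestedGLMM", "GLMMResult", "ConvergenceError"]

# linear predictors beyond this are clipped inside exp/expit guards
_ETA_CAP = 300.0


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the gradient tolerance; carries diagnostics."""

    def __init__(self, message, grad_norm=None):
        super().__init__(message)
        self.grad_norm = grad_norm


@dataclass(frozen=True)
class CovStructure:
    """Parameterization of one level's random-effect covariance.

    kinds
    -----
    ``scalar``  one variance (random intercept only);
    ``pair``    2x2 with correlation, params (log sd0, log sd1, atanh rho);
    ``diag``    q independent components, params (log sd_1..log sd_q).
    """

    kind: str
    q: int

    @property
    def n_params(self) -> int:
        return {"scalar": 1, "pair": 3, "diag": self.q}[self.kind]

    def init(self) -> np.ndarray:
        if self.kind == "scalar":
            return np.array([np.log(0.15)])
        if self.kind == "pair":
            return np.array([np.log(0.15), np.log(0.05), 0.0])
        return np.full(self.q, np.log(0.15))

    def bounds(self) -> list[tuple[float, float]]:
        b = [(-7.0, 3.0)] * self.n_params
        if self.kind == "pair":
            b[2] = (-5.0, 5.0)
        return b

    def cov(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, float)
        if self.kind == "scalar":
            return np.array([[np.exp(2.0 * theta[0])]])
        if self.kind == "pair":
            s0, s1 = np.exp(theta[0]), np.exp(theta[1])
            rho = np.tanh(theta[2])
            return np.array([[s0 * s0, rho * s0 * s1], [rho * s0 * s1, s1 * s1]])
        return np.diag(np.exp(2.0 * theta))

    def from_cov(self, cov: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`cov` (used for warm starts); clips to bounds."""
        cov = np.atleast_2d(cov)
        sd = np.sqrt(np.clip(np.diag(cov), 1e-12, None))
        if self.kind == "scalar":
            theta = np.array([np.log(sd[0])])
        elif self.kind == "pair":
            rho = np.clip(cov[0, 1] / (sd[0] * sd[1]), -0.999, 0.999)
            theta = np.array([np.log(sd[0]), np.log(sd[1]), np.arctanh(rho)])
        else:
            theta = np.log(sd)
        lo = np.array([b[0] for b in self.bounds()])
        hi = np.array([b[1] for b in self.bounds()])
        return np.clip(theta, lo, hi)


# ---------------------------------------------------------------------------
# families


def _poisson_loglik(eta_tot, y, _):
    eta_tot = np.clip(eta_tot, -_ETA_CAP, _ETA_CAP)
    return y * eta_tot - np.exp(eta_tot) - special.gammaln(y + 1.0)


def _poisson_derivs(eta_tot, y, _):
    lam = np.exp(np.clip(eta_tot, -_ETA_CAP, _ETA_CAP))
    return y - lam, lam


def _binomial_loglik(eta, y, n):
    ll = y * eta - n * np.logaddexp(0.0, eta)
    return ll + special.gammaln(n + 1) - special.gammaln(y + 1) - special.gammaln(n - y + 1)


def _binomial_derivs(eta, y, n):
    p = special.expit(eta)
    return y - n * p, np.clip(n * p * (1.0 - p), 1e-12, None)


def _normal_loglik(eta, y, v):
    return -0.5 * ((y - eta) ** 2 / v + np.log(2.0 * np.pi * v))


def _normal_derivs(eta, y, v):
    return (y - eta) / v, 1.0 / v


_FAMILIES = {
    "poisson": (_poisson_loglik, _poisson_derivs),
    "binomial": (_binomial_loglik, _binomial_derivs),
    "normal_known_variance": (_normal_loglik, _normal_derivs),
}


@dataclass
class GLMMResult:
    beta: np.ndarray
    beta_cov: np.ndarray
    theta_c: np.ndarray
    theta_s: np.ndarray
    cov_county: np.ndarray  # (q, q) estimated county-level covariance
    cov_state: np.ndarray
    u_county: np.ndarray  # (C, q) EB conditional means
    u_state: np.ndarray  # (K, q)
    eb_cov_county: np.ndarray  # (C, q, q) EB conditional covariances
    eb_cov_state: np.ndarray  # (K, q, q)
    loglik: float
    converged: bool
    grad_norm: float
    n_outer_iter: int


class NestedGLMM:
    """Two-level nested GLMM with shared random design at both levels.

    Parameters
    ----------
    X : (N, p) fixed-effect design.
    Z : (N, q) random-effect design (used at both the state and county level).
    y : (N,) response (counts, successes, or known-variance observations).
    aux : (N,) family auxiliary: Poisson offset's exp, i.e. exposure ``n``;
        binomial trials ``n``; known variance for the normal family.
    county : (N,) integer county index into a roster of C counties, which must
        be grouped by state (all counties of a state contiguous).
    county_state : (C,) integer state index per county, nondecreasing.
    family : {"poisson", "binomial", "normal_known_variance"}.
    struct_c, struct_s : covariance structures for the county / state level.
    """

    def __init__(self, X, Z, y, aux, county, county_state, family, struct_c, struct_s):
        order = np.argsort(county, kind="stable")
        self.X = np.asarray(X, float)[order]
        self.Z = np.asarray(Z, float)[order]
        self.y = np.asarray(y, float)[order]
        self.aux = np.asarray(aux, float)[order]
        self.county = np.asarray(county)[order]
        self.county_state = np.asarray(county_state)
        if np.any(np.diff(self.county_state) < 0):
            raise ValueError("counties must be grouped by state")
        self.state_obs = self.county_state[self.county]
        self.C = len(self.county_state)
        self.K = int(self.county_state.max()) + 1 if self.C else 0
        self.N, self.p = self.X.shape
        self.q = self.Z.shape[1]
        if family not in _FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        self.family = family
        self._ll, self._dv = _FAMILIES[family]
        if family == "poisson":
            self.offset = np.log(self.aux)
        else:
            self.offset = np.zeros(self.N)
        self.struct_c = struct_c
        self.struct_s = struct_s
        if struct_c.q != self.q or struct_s.q != self.q:
            raise ValueError("structure dimension must match random design")
        # upper-triangle index pairs for batched Z Z' aggregation
        self._pairs = [(r, s) for r in range(self.q) for s in range(r, self.q)]
        self._uc = np.zeros((self.C, self.q))
        self._us = np.zeros((self.K, self.q))

    # -- inner problem -----------------------------------------------------

    def _eta(self, beta, uc, us):
        eta = self.X @ beta
        eta += np.einsum("nq,nq->n", self.Z, uc[self.county])
        eta += np.einsum("nq,nq->n", self.Z, us[self.state_obs])
        return eta

    def _obs_loglik(self, eta):
        if self.family == "poisson":
            return self._ll(eta + self.offset, self.y, None)
        return self._ll(eta, self.y, self.aux)

    def _obs_derivs(self, eta):
        if self.family == "poisson":
            return self._dv(eta + self.offset, self.y, None)
        return self._dv(eta, self.y, self.aux)

    def _agg_county(self, w):
        """Sum per-observation weights into county bins (handles empty counties)."""
        return np.bincount(self.county, weights=w, minlength=self.C)

    def _segsum_state(self, arr):
        """Sum a county-indexed array over states."""
        out = np.zeros((self.K,) + arr.shape[1:])
        np.add.at(out, self.county_state, arr)
        return out

    def _penalized(self, beta, uc, us, Lc_inv, Ls_inv):
        eta = self._eta(beta, uc, us)
        ll = self._obs_loglik(eta).sum()
        quad = np.sum(uc * (uc @ Lc_inv)) + np.sum(us * (us @ Ls_inv))
        return ll - 0.5 * quad

    def _inner_newton(self, beta, Lc_inv, Ls_inv, max_iter=100, tol=1e-13):
        """Maximize the penalized joint log-density over all random effects.

        Returns the modes, penalized value, log|H| and the factorization
        pieces needed for EB covariances. Globally convergent for the three
        (log-concave) families via step halving.
        """
        uc, us = self._uc.copy(), self._us.copy()
        f = self._penalized(beta, uc, us, Lc_inv, Ls_inv)
        if not np.isfinite(f):
            uc[:] = 0.0
            us[:] = 0.0
            f = self._penalized(beta, uc, us, Lc_inv, Ls_inv)
        pieces = None
        for _ in range(max_iter):
            eta = self._eta(beta, uc, us)
            grad, W = self._obs_derivs(eta)
            # county-level gradient and curvature blocks
            Gc = np.stack([self._agg_county(grad * self.Z[:, r]) for r in range(self.q)], axis=1)
            g_c = Gc - uc @ Lc_inv
            Dbase = np.zeros((self.C, self.q, self.q))
            for r, s in self._pairs:
                v = self._agg_county(W * self.Z[:, r] * self.Z[:, s])
                Dbase[:, r, s] = v
                if r != s:
                    Dbase[:, s, r] = v
            D = Dbase + Lc_inv
            B = Dbase  # state/county cross blocks coincide with shared Z
            A = self._segsum_state(Dbase) + Ls_inv
            g_s = self._segsum_state(Gc) - us @ Ls_inv

            Dchol = np.linalg.cholesky(D)
            Dinv = np.linalg.inv(D)
            BDinv = np.einsum("cij,cjk->cik", B, Dinv)
            S = A - self._segsum_state(np.einsum("cij,cjk->cik", BDinv, B))
            gtil = g_s - self._segsum_state(np.einsum("cij,cj->ci", BDinv, g_c))
            Schol = np.linalg.cholesky(S)
            ds = np.linalg.solve(S, gtil[..., None])[..., 0]
            dc = np.einsum(
                "cij,cj->ci", Dinv, g_c - np.einsum("cij,cj->ci", B, ds[self.county_state])
            )
            dec = float(np.sum(g_c * dc) + np.sum(g_s * ds))
            pieces = (Dchol, Dinv, B, S, Schol)
            if dec < tol * (1.0 + abs(f)):
                break
            step = 1.0
            while step > 1e-10:
                uc_n = uc + step * dc
                us_n = us + step * ds
                f_n = self._penalized(beta, uc_n, us_n, Lc_inv, Ls_inv)
                if np.isfinite(f_n) and f_n >= f - 1e-12 * (1 + abs(f)):
                    break
                step *= 0.5
            if f_n < f and step <= 1e-10:
                break
            uc, us, f = uc_n, us_n, f_n
        self._uc, self._us = uc, us
        Dchol, Dinv, B, S, Schol = pieces
        logdet_h = 2.0 * (
            np.log(np.diagonal(Dchol, axis1=1, axis2=2)).sum()
            + np.log(np.diagonal(Schol, axis1=1, axis2=2)).sum()
        )
        return uc, us, f, logdet_h, (Dinv, B, S)

    # -- marginal likelihood ----------------------------------------------

    def _lambda_pieces(self, theta_c, theta_s):
        Lc = self.struct_c.cov(theta_c)
        Ls = self.struct_s.cov(theta_s)
        Lc_inv = np.linalg.inv(Lc)
        Ls_inv = np.linalg.inv(Ls)
        _, ld_c = np.linalg.slogdet(Lc)
        _, ld_s = np.linalg.slogdet(Ls)
        return Lc_inv, Ls_inv, ld_c, ld_s

    def marginal_loglik(self, beta, theta_c, theta_s):
        """Laplace-approximate marginal log-likelihood (exact for the normal family)."""
        Lc_inv, Ls_inv, ld_c, ld_s = self._lambda_pieces(theta_c, theta_s)
        _, _, f, logdet_h, _ = self._inner_newton(beta, Lc_inv, Ls_inv)
        return f - 0.5 * (self.C * ld_c + self.K * ld_s) - 0.5 * logdet_h

    def _pack(self, beta, theta_c, theta_s):
        return np.concatenate([beta, theta_c, theta_s])

    def _unpack(self, x):
        p, nc = self.p, self.struct_c.n_params
        return x[:p], x[p : p + nc], x[p + nc :]

    def _neg(self, x):
        beta, tc, ts = self._unpack(x)
        try:
            val = self.marginal_loglik(beta, tc, ts)
        except np.linalg.LinAlgError:
            return 1e12
        if not np.isfinite(val):
            return 1e12
        return -val

    def _beta_start(self):
        """Fixed-effects-only GLM start via a few IRLS steps."""
        beta = np.zeros(self.p)
        if self.family == "poisson":
            rate = (self.y + 0.5) / self.aux
            z = np.log(rate)
        elif self.family == "binomial":
            p = (self.y + 0.5) / (self.aux + 1.0)
            z = np.log(p / (1 - p))
        else:
            z = self.y
        beta, *_ = np.linalg.lstsq(self.X, z, rcond=None)
        for _ in range(5 if self.family != "normal_known_variance" else 0):
            eta = self.X @ beta
            grad, W = self._obs_derivs(eta)
            H = self.X.T @ (W[:, None] * self.X)
            g = self.X.T @ grad
            try:
                beta = beta + np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
        return beta

    def fit(
        self,
        beta0=None,
        theta_c0=None,
        theta_s0=None,
        gtol=1e-5,
        maxiter=500,
        n_restarts=2,
        polish=None,
        seed=0,
    ) -> GLMMResult:
        """Maximize the marginal likelihood; returns estimates and EB blocks.

        The outer quasi-Newton works on the unconstrained parameterization
        (beta, log sd, atanh rho) with bound guards well outside any
        plausible optimum. If the projected gradient fails the tolerance the
        optimizer restarts from a perturbed point (up to ``n_restarts``
        times) and keeps the best solution; a final Newton polish with
        central differences sharpens the optimum when the parameter count is
        small (``polish=None`` enables it for <= 12 parameters).
        """
        beta0 = self._beta_start() if beta0 is None else np.asarray(beta0, float)
        tc0 = self.struct_c.init() if theta_c0 is None else np.asarray(theta_c0, float)
        ts0 = self.struct_s.init() if theta_s0 is None else np.asarray(theta_s0, float)
        x0 = self._pack(beta0, tc0, ts0)
        bounds = [(None, None)] * self.p + self.struct_c.bounds() + self.struct_s.bounds()
        rng = np.random.default_rng(seed)

        best = None
        x_start = x0
        n_iter = 0
        for attempt in range(n_restarts + 1):
            self._uc[:] = 0.0
            self._us[:] = 0.0
            res = optimize.minimize(
                self._neg,
                x_start,
                method="L-BFGS-B",
                bounds=bounds,
                options={
                    "maxiter": maxiter,
                    "ftol": 1e-12,
                    "gtol": gtol,
                    "eps": 1e-6,
                    "maxcor": 25,
                },
            )
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
            gnorm = float(np.max(np.abs(res.jac)))
            if gnorm < max(gtol, 1e-4 * (1 + abs(res.fun))) and res.fun < 1e11:
                break
            x_start = best.x + rng.normal(0.0, 0.05, size=best.x.size)

        x = best.x
        if polish is None:
            polish = x.size <= 12
        decrement = None
        if polish:
            x, decrement = self._polish(x, bounds)
        beta, tc, ts = self._unpack(x)
        loglik = self.marginal_loglik(beta, tc, ts)
        g_proj = self._projected_grad(x, bounds)
        grad_norm = float(np.max(np.abs(g_proj)))
        # convergence: the Newton decrement (estimated remaining improvement)
        # is scale-free; without it fall back to a loglik-scaled projected
        # gradient norm (bound-pinned variance parameters excluded)
        if decrement is not None:
            converged = bool(np.isfinite(loglik)) and decrement < 1e-5 * (1 + abs(loglik))
        else:
            converged = bool(np.isfinite(loglik)) and grad_norm < max(
                1e-2, 3e-4 * (1 + abs(loglik))
            )

        beta_cov = self._beta_cov(beta, tc, ts)
        Lc_inv, Ls_inv, _, _ = self._lambda_pieces(tc, ts)
        uc, us, _, _, (Dinv, B, S) = self._inner_newton(beta, Lc_inv, Ls_inv)
        Sinv = np.linalg.inv(S)
        eb_cov_state = Sinv
        M = np.einsum("cij,cjk->cik", Dinv, B)  # D^-1 B' (B symmetric)
        eb_cov_county = Dinv + np.einsum(
            "cij,cjk,clk->cil", M, Sinv[self.county_state], M
        )
        # symmetrize against roundoff
        eb_cov_county = 0.5 * (eb_cov_county + np.swapaxes(eb_cov_county, 1, 2))
        return GLMMResult(
            beta=beta,
            beta_cov=beta_cov,
            theta_c=tc,
            theta_s=ts,
            cov_county=self.struct_c.cov(tc),
            cov_state=self.struct_s.cov(ts),
            u_county=uc,
            u_state=us,
            eb_cov_county=eb_cov_county,
            eb_cov_state=eb_cov_state,
            loglik=float(loglik),
            converged=converged,
            grad_norm=grad_norm,
            n_outer_iter=int(n_iter),
        )

    # -- derivative helpers -------------------------------------------------

    @staticmethod
    def _bounds_arrays(bounds):
        lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
        hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
        return lo, hi

    def _projected_grad(self, x, bounds, h=1e-5):
        """Gradient of the objective with infeasible descent directions zeroed
        (a parameter pinned at a bound cannot be improved past it)."""
        lo, hi = self._bounds_arrays(bounds)
        g = self._fd_grad(x, h=h)
        at_lo = x <= lo + 1e-8
        at_hi = x >= hi - 1e-8
        g = g.copy()
        g[at_lo & (g > 0)] = 0.0
        g[at_hi & (g < 0)] = 0.0
        return g

    def _fd_grad(self, x, h=1e-5):
        g = np.zeros_like(x)
        for i in range(x.size):
            e = np.zeros_like(x)
            e[i] = h
            g[i] = (self._neg(x + e) - self._neg(x - e)) / (2 * h)
        return g

    def _fd_hess(self, x, h=1e-4):
        n = x.size
        H = np.zeros((n, n))
        f0 = self._neg(x)
        for i in range(n):
            ei = np.zeros(n)
            ei[i] = h
            for j in range(i, n):
                ej = np.zeros(n)
                ej[j] = h
                if i == j:
                    H[i, i] = (self._neg(x + ei) - 2 * f0 + self._neg(x - ei)) / h**2
                else:
                    H[i, j] = H[j, i] = (
                        self._neg(x + ei + ej)
                        - self._neg(x + ei - ej)
                        - self._neg(x - ei + ej)
                        + self._neg(x - ei - ej)
                    ) / (4 * h**2)
        return H

    def _polish(self, x, bounds, n_steps=12):
        """Newton refinement with central-difference derivatives; returns the
        refined point and the final Newton decrement g'H^-1 g / 2."""
        lo, hi = self._bounds_arrays(bounds)
        f = self._neg(x)
        decrement = np.inf
        for _ in range(n_steps):
            g = self._projected_grad(x, bounds)
            H = self._fd_hess(x)
            # keep the step well-posed even at variance boundaries
            w, V = np.linalg.eigh(H)
            w = np.clip(w, 1e-6 * max(1.0, w.max()), None)
            step = V @ ((V.T @ g) / w)
            decrement = 0.5 * float(g @ step)
            if decrement < 1e-9 * (1 + abs(f)):
                break
            for damp in (1.0, 0.5, 0.25, 0.1):
                x_n = np.clip(x - damp * step, lo, hi)
                f_n = self._neg(x_n)
                if f_n <= f + 1e-12 * (1 + abs(f)):
                    break
            if f_n > f:
                break
            x, f = x_n, f_n
        return x, max(decrement, 0.0)

    def _beta_cov(self, beta, theta_c, theta_s, h=1e-4):
        """Covariance of the fixed effects: inverse observed information of the
        Laplace marginal likelihood in beta, holding variance parameters at
        their estimates (empirical-Bayes convention)."""
        p = self.p

        def negb(b):
            return -self.marginal_loglik(b, theta_c, theta_s)

        H = np.zeros((p, p))
        f0 = negb(beta)
        hs = h * (1.0 + np.abs(beta))
        for i in range(p):
            ei = np.zeros(p)
            ei[i] = hs[i]
            for j in range(i, p):
                ej = np.zeros(p)
                ej[j] = hs[j]
                if i == j:
                    H[i, i] = (negb(beta + ei) - 2 * f0 + negb(beta - ei)) / hs[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        negb(beta + ei + ej)
                        - negb(beta + ei - ej)
                        - negb(beta - ei + ej)
                        + negb(beta - ei - ej)
                    ) / (4 * hs[i] * hs[j])
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
        return 0.5 * (cov + cov.T)
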