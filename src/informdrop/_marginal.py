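"""Profiled-likelihood engine for marginal random-coefficients models.

Every longitudinal sub-model in this package is of the form

    y_i ~ N(X_i beta, V_i),   V_i = Z_i G Z_i' + sigma^2 I,   Z_i = [1, t]

with subject-specific design X_i (3 columns for the plain model, 3K for the
pattern-stratified one).  For fixed variance components the fixed effects
have a closed-form GLS solution, so fitting profiles beta out and optimizes
a 4-parameter unconstrained criterion: the log-Cholesky factor of G
(diagonal on the log scale) plus log sigma^2, which guarantees positive
(semi-)definiteness without constraints.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg, optimize

_LOG2PI = np.log(2.0 * np.pi)

# Unconstrained optimization bounds: log-sd of random effects in
# [e-10, e8] and log residual variance in [-24, 12] -- wide enough for
# 0-100 point scores while keeping V numerically positive definite.
THETA_BOUNDS = ((-10.0, 8.0), (-500.0, 500.0), (-10.0, 8.0), (-24.0, 12.0))


def chol_from_theta(theta):
    """theta = (a, l21, c, log_s2) -> (L, G, sigma2) with G = L L'."""
    a, l21, c, log_s2 = theta
    L = np.array([[np.exp(a), 0.0], [l21, np.exp(c)]])
    return L, L @ L.T, float(np.exp(log_s2))


def theta_from(G, sigma2, floor=1e-8):
    """Inverse of :func:`chol_from_theta`, with a jitter floor for G ~ 0."""
    G = np.asarray(G, dtype=float)
    Gj = G + floor * np.eye(2)
    L = np.linalg.cholesky(Gj)
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1]),
                     np.log(max(float(sigma2), floor))])


@dataclasses.dataclass
class Group:
    """Subjects sharing one observed-time support: Y (m, d), X (m, d, p)."""

    times: np.ndarray
    Y: np.ndarray
    X: np.ndarray


@dataclasses.dataclass
class EngineFit:
    theta: np.ndarray
    beta: np.ndarray
    vcov_beta: np.ndarray
    loglik: float
    method: str
    converged: bool
    message: str
    n_iter: int


def build_groups(scores, times_all, X_rows):
    """Group subjects by availability mask.

    ``scores``: (n, J) with NaN missing; ``times_all``: (J,) planned times;
    ``X_rows``: (n, J, p) full design rows (rows for missing visits ignored).
    """
    scores = np.asarray(scores, dtype=float)
    X_rows = np.asarray(X_rows, dtype=float)
    obs = np.isfinite(scores)
    keys = {}
    for i in range(scores.shape[0]):
        keys.setdefault(tuple(obs[i]), []).append(i)
    groups = []
    index_order = []
    for mask, idx in keys.items():
        mask = np.asarray(mask)
        idx = np.asarray(idx)
        groups.append(Group(times=np.asarray(times_all)[mask],
                            Y=scores[np.ix_(idx, np.flatnonzero(mask))],
                            X=X_rows[np.ix_(idx, np.flatnonzero(mask))]))
        index_order.append(idx)
    return groups, index_order


class MarginalProblem:
    """Likelihood machinery over a fixed grouping of subjects."""

    def __init__(self, groups):
        self.groups = [g for g in groups if g.Y.shape[0] > 0]
        if not self.groups:
            raise ValueError("no subjects")
        self.p = self.groups[0].X.shape[2]
        self.n_obs = int(sum(g.Y.size for g in self.groups))
        self.n_subjects = int(sum(g.Y.shape[0] for g in self.groups))

    # -- per-theta sufficient statistics -------------------------------
    def _stats(self, theta):
        _, G, s2 = chol_from_theta(theta)
        return self._stats_at(G, s2)

    def _stats_at(self, G, s2):
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        q = 0.0
        sum_logdet = 0.0
        for g in self.groups:
            d = g.times.size
            Z = np.column_stack([np.ones(d), g.times])
            V = Z @ G @ Z.T + s2 * np.eye(d)
            cf = linalg.cho_factor(V, lower=True)
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            Vinv = linalg.cho_solve(cf, np.eye(d))
            A += np.einsum("mdi,de,mej->ij", g.X, Vinv, g.X)
            b += np.einsum("mdi,de,me->i", g.X, Vinv, g.Y)
            q += float(np.einsum("md,de,me->", g.Y, Vinv, g.Y))
            sum_logdet += g.Y.shape[0] * logdet
        return A, b, q, sum_logdet

    def profiled_loglik(self, theta, method="REML"):
        """Log-likelihood at theta with beta profiled out by GLS."""
        try:
            A, b, q, sum_logdet = self._stats(theta)
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return -np.inf, None
        rss = q - beta @ b
        if method == "ML":
            ll = -0.5 * (self.n_obs * _LOG2PI + sum_logdet + rss)
        elif method == "REML":
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return -np.inf, None
            ll = -0.5 * ((self.n_obs - self.p) * _LOG2PI + sum_logdet
                         + logdetA + rss)
        else:
            raise ValueError(f"unknown method {method!r}")
        return float(ll), beta

    def loglik_at(self, beta, G, sigma2, method="ML"):
        """Log-likelihood at explicit (beta, G, sigma2).

        The REML criterion is a likelihood of error contrasts and does not
        depend on beta; the supplied beta is ignored in that case.
        """
        A, b, q, sum_logdet = self._stats_at(np.asarray(G, dtype=float),
                                             float(sigma2))
        if method == "REML":
            bh = np.linalg.solve(A, b)
            rss = q - bh @ b
            sign, logdetA = np.linalg.slogdet(A)
            return float(-0.5 * ((self.n_obs - self.p) * _LOG2PI + sum_logdet
                                 + logdetA + rss))
        beta = np.asarray(beta, dtype=float)
        rss = q - 2.0 * beta @ b + beta @ A @ beta
        return float(-0.5 * (self.n_obs * _LOG2PI + sum_logdet + rss))

    def gls(self, theta):
        """(beta_hat, vcov) at fixed variance components."""
        A, b, _, _ = self._stats(theta)
        beta = np.linalg.solve(A, b)
        return beta, np.linalg.inv(A)

    # -- fitting --------------------------------------------------------
    def start_theta(self):
        """Moment-based start: split the OLS residual variance."""
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        for g in self.groups:
            A += np.einsum("mdi,mdj->ij", g.X, g.X)
            b += np.einsum("mdi,md->i", g.X, g.Y)
        beta = np.linalg.lstsq(A, b, rcond=None)[0]
        rss = 0.0
        for g in self.groups:
            r = g.Y - g.X @ beta
            rss += float((r * r).sum())
        v = max(rss / max(self.n_obs - self.p, 1), 1e-6)
        tmax = max(max(abs(g.times).max() for g in self.groups), 1.0)
        G0 = np.diag([v / 2.0, v / (2.0 * tmax ** 2)])
        return theta_from(G0, v / 2.0)

    def fit(self, method="REML", start=None, n_starts=3, seed=0):
        """Maximize the profiled criterion; jittered restarts on failure."""
        x0 = np.asarray(start, dtype=float) if start is not None else self.start_theta()
        rng = np.random.default_rng(seed)
        best = None
        for attempt in range(n_starts):
            xa = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.5, size=4)
            xa = np.clip(xa, [lo for lo, _ in THETA_BOUNDS],
                         [hi for _, hi in THETA_BOUNDS])

            def objective(th):
                # finite penalty: a non-finite value aborts the line search
                ll = self.profiled_loglik(th, method)[0]
                return -ll if np.isfinite(ll) else 1e15

            res = optimize.minimize(
                objective, xa, method="L-BFGS-B", bounds=THETA_BOUNDS,
                options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 500},
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
            if res.success:
                best = res if res.fun <= best.fun + 1e-10 else best
                break
        theta = best.x
        ll, beta = self.profiled_loglik(theta, method)
        _, vcov = self.gls(theta)
        return EngineFit(theta=theta, beta=beta, vcov_beta=vcov, loglik=ll,
                         method=method, converged=bool(best.success),
                         message=str(best.message), n_iter=int(best.nit))
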