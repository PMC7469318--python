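"""Shared-parameter joint model of score trajectories and time-to-dropout.

The longitudinal scores and the dropout time are assumed conditionally
independent given the subject's random effects b = (b0, b1).  Dropout is a
continuous-time proportional-hazards process with a piecewise-constant
baseline hazard and a current-value association:

    lambda(t | arm, b) = xi_q(t) * exp{gamma * arm + alpha * Y*(t)}
    Y*(t) = beta0 + b0 + (beta1 + beta2 * arm + b1) * t

where Y*(t) is the error-free (true) score.  The default baseline hazard
has seven intervals with internal knots at months 1.25, 3, 4, 6, 12, 24.
Because Y* is linear in t, the cumulative hazard has a closed form on each
interval.  The observed-data likelihood integrates over b with adaptively
centered Gauss-Hermite quadrature (9 nodes per dimension by default); a
pseudo-adaptive variant with nodes fixed at a preliminary fit's
empirical-Bayes posteriors is available via :func:`pseudo_adaptive_config`.

The dropout time is the delay from inclusion to the last visit with an
available score; completers are administratively censored at the final
planned visit.  Because every recorded event time lies on the visit grid,
the default likelihood treats dropout as interval-censored between the
last available and the first missed visit (P = S(t_D) - S(t_{D+1}) given
b); evaluating the hazard density at the recorded time instead
(``form="exact"``) is supported but its likelihood is unbounded in alpha
on gridded event times and is meant for diagnostics and the alpha = 0
decoupling limit.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import optimize, special

from . import _marginal, _numdiff
from .core_data import TrialDataset
from .lmm import LMMParams, eb_estimates, fit_lmm

_LOG = logging.getLogger(__name__)
_LOG2PI = np.log(2.0 * np.pi)

DEFAULT_KNOTS = (1.25, 3.0, 4.0, 6.0, 12.0, 24.0)


@dataclasses.dataclass
class SPMParams:
    """Longitudinal parameters plus hazard sub-model parameters."""

    lmm: LMMParams
    gamma: float                 # arm effect on the log-hazard of dropout
    alpha: float                 # association, per score point
    xi: np.ndarray               # baseline-hazard levels (events/month)
    knots: tuple = DEFAULT_KNOTS

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        self.knots = tuple(float(k) for k in self.knots)
        if self.xi.size != len(self.knots) + 1:
            raise ValueError("need len(knots) + 1 baseline-hazard levels")
        if (self.xi <= 0).any():
            raise ValueError("baseline-hazard levels must be positive")

    @property
    def Q(self) -> int:
        return self.xi.size

    def interval_edges(self):
        """Left edges including 0; intervals are left-closed, right-open,
        the last one open-ended."""
        return np.concatenate([[0.0], np.asarray(self.knots)])


@dataclasses.dataclass
class DropoutTime:
    T: np.ndarray                # months, time of last available visit
    event: np.ndarray            # 1 = dropped before the final visit


@dataclasses.dataclass
class SPMFit:
    params: SPMParams
    se_beta: np.ndarray
    se_gamma: float
    se_alpha: float
    se_log_xi: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    hessian_ok: bool
    quad_nodes: int
    n_events: int
    n_iter: int = 0


@dataclasses.dataclass
class GHConfig:
    """Two-dimensional (tensor) Gauss-Hermite rule over the random effects.

    ``centering`` is an optional (modes (n, 2), covariances (n, 2, 2)) pair;
    when absent, nodes are centered at the empirical-Bayes posterior implied
    by the parameters being evaluated (fully adaptive)."""

    n_nodes: int = 9
    centering: tuple | None = None


def current_value(lmm: LMMParams, b, arm, t):
    """Error-free trajectory value Y*(t) = E[Y(t) | b] for one subject."""
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    slope = lmm.beta1 + lmm.beta2 * float(arm) + b[1]
    return lmm.beta0 + b[0] + slope * t


def interval_index(knots, t):
    """0-based index of the baseline-hazard interval containing t."""
    return np.searchsorted(np.asarray(knots, dtype=float), np.asarray(t, float),
                           side="right")


def hazard(params: SPMParams, b, arm, t):
    """Instantaneous dropout hazard (events/month) at time t."""
    q = interval_index(params.knots, t)
    ystar = current_value(params.lmm, b, arm, t)
    return params.xi[q] * np.exp(params.gamma * float(arm) + params.alpha * ystar)


def _segment_integral(alpha_s, lo, hi):
    """int_lo^hi exp(alpha_s * u) du, stable as alpha_s -> 0."""
    alpha_s = np.asarray(alpha_s, dtype=float)
    length = np.asarray(hi, float) - np.asarray(lo, float)
    small = np.abs(alpha_s * np.maximum(length, 1.0)) < 1e-10
    with np.errstate(divide="ignore", invalid="ignore"):
        val = np.exp(alpha_s * np.asarray(lo, float)) * np.expm1(alpha_s * length) / alpha_s
    return np.where(small, length * np.exp(alpha_s * np.asarray(lo, float)), val)


def cumulative_hazard(params: SPMParams, b, arm, t):
    """Closed-form cumulative hazard: with Y* linear in time, each interval's
    integral is analytic; the limit alpha*slope -> 0 reduces to the
    piecewise-exponential form."""
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    edges = params.interval_edges()
    slope = params.lmm.beta1 + params.lmm.beta2 * float(arm) + b[1]
    level = params.lmm.beta0 + b[0]
    scale = np.exp(params.gamma * float(arm) + params.alpha * level)
    a_s = params.alpha * slope
    total = np.zeros(t.shape) if t.shape else 0.0
    for q in range(params.Q):
        lo = edges[q]
        hi = edges[q + 1] if q + 1 < edges.size else np.inf
        up = np.minimum(t, hi)
        seg = np.where(up > lo, _segment_integral(a_s, lo, np.maximum(up, lo)), 0.0)
        total = total + params.xi[q] * scale * seg
    return total if total.shape else float(total)


def dropout_times(dataset: TrialDataset) -> DropoutTime:
    """Time of last available visit; event iff the subject is not a completer
    (completers are censored at the final planned visit)."""
    t = dataset.schedule.times_array()
    D = dataset.dropout_index
    return DropoutTime(T=t[D - 1], event=(D < dataset.schedule.J).astype(int))


# ----------------------------------------------------------------------
# piecewise-exponential survival model (alpha = 0 limit; also used for
# initialization of the joint fit)

def _exposure_matrix(T, knots):
    T = np.asarray(T, dtype=float)
    edges = np.concatenate([[0.0], np.asarray(knots, float), [np.inf]])
    Q = len(knots) + 1
    E = np.zeros((T.size, Q))
    for q in range(Q):
        E[:, q] = np.clip(np.minimum(T, edges[q + 1]) - edges[q], 0.0, None)
    return E


def piecewise_exponential_loglik(xi, gamma, knots, T, event, arm):
    """Log-likelihood of the dropout times under the baseline + arm model."""
    xi = np.asarray(xi, dtype=float)
    T = np.asarray(T, dtype=float)
    event = np.asarray(event)
    arm = np.asarray(arm, dtype=float)
    E = _exposure_matrix(T, knots)
    lam_scale = np.exp(gamma * arm)
    cum = (E @ xi) * lam_scale
    q_at = interval_index(knots, T)
    log_haz = np.log(xi[q_at]) + gamma * arm
    return float((event * log_haz).sum() - cum.sum())


def fit_piecewise_exponential(T, event, arm, knots=DEFAULT_KNOTS):
    """Profile fit: for fixed gamma, xi_q = D_q / sum_i exp(gamma arm_i) E_iq."""
    T = np.asarray(T, dtype=float)
    event = np.asarray(event)
    arm = np.asarray(arm, dtype=float)
    E = _exposure_matrix(T, knots)
    q_at = interval_index(knots, T)
    Q = len(knots) + 1
    D_q = np.array([(event * (q_at == q)).sum() for q in range(Q)], dtype=float)

    def xi_of(g):
        denom = (np.exp(g * arm)[:, None] * E).sum(axis=0)
        return np.maximum(D_q, 0.25) / np.maximum(denom, 1e-12)

    def neg_profile(g):
        g = float(g)
        return -piecewise_exponential_loglik(xi_of(g), g, knots, T, event, arm)

    res = optimize.minimize_scalar(neg_profile, bounds=(-5.0, 5.0), method="bounded")
    g = float(res.x)
    return xi_of(g), g


# ----------------------------------------------------------------------
# joint likelihood

class _SPMContext:
    """Precomputation for repeated joint-likelihood evaluation.

    Two quadrature strategies share the survival-factor code:

    * adaptive (default, ``centering=None``): per evaluation, nodes are
      placed at the exact empirical-Bayes posterior of b implied by the
      current longitudinal parameters.  The Gaussian factors then integrate
      exactly -- the subject contribution is the marginal normal density
      times a weighted average of the survival factor over posterior nodes
      -- so the rule cannot reward parameter regions where it is inaccurate.
    * pseudo-adaptive (``centering=(modes, covs)``): nodes fixed at a
      preliminary fit's posteriors, with importance reweighting.  Cheaper
      per evaluation but the reweighting can be badly served by extreme
      survival parameters; kept as an option and for the degenerate cases.
    """

    def __init__(self, dataset: TrialDataset, quad: GHConfig, centering=None,
                 form: str = "interval"):
        if form not in ("interval", "exact"):
            raise ValueError(f"unknown dropout-likelihood form {form!r}")
        self.form = form
        self.J = dataset.schedule.J
        self.n = dataset.n_subjects
        self.arm = dataset.arm.astype(float)
        self.edge_cache = {}
        dt = dropout_times(dataset)
        self.T, self.event = dt.T, dt.event
        t_all = dataset.schedule.times_array()
        D = dataset.dropout_index
        # first missed visit (upper interval endpoint); completers unused
        self.T_next = t_all[np.minimum(D, self.J - 1)]
        self.t_max = max(float(self.T.max()), 1.0)

        x1, w1 = special.roots_hermite(quad.n_nodes)
        self.U = np.stack(np.meshgrid(x1, x1, indexing="ij"), axis=-1).reshape(-1, 2)
        self.W = np.outer(w1, w1).reshape(-1)
        self.Kq = self.U.shape[0]

        # group subjects by availability mask (monotone data: by D)
        obs = dataset.observed
        keys = {}
        for i in range(dataset.n_subjects):
            keys.setdefault(tuple(obs[i]), []).append(i)
        self.groups = []
        for mask, idx in keys.items():
            idx = np.asarray(idx)
            cols = np.flatnonzero(np.asarray(mask))
            tt = t_all[cols]
            arm = dataset.arm[idx].astype(float)
            d = cols.size
            X = np.empty((idx.size, d, 3))
            X[:, :, 0] = 1.0
            X[:, :, 1] = tt[None, :]
            X[:, :, 2] = arm[:, None] * tt[None, :]
            self.groups.append({
                "idx": idx, "times": tt, "arm": arm, "X": X,
                "Z": np.column_stack([np.ones(d), tt]),
                "Y": dataset.scores[np.ix_(idx, cols)],
                "T": self.T[idx], "T_next": self.T_next[idx],
                "event": self.event[idx],
                "edge_cache": {},
            })

        self._post_cache_key = None
        self.centering = None
        if centering is not None:
            modes, covs = centering
            covs = np.asarray(covs)
            if covs.shape[-2:] != (2, 2):
                raise ValueError("centering covariances must be (n, 2, 2)")
            L = np.linalg.cholesky(covs)
            self.centering = (np.asarray(modes), L)

    def _clipped_edges(self, knots, which, arr_T, arr_Tn, cache):
        key = (tuple(knots), which)
        if key not in cache:
            edges = np.append(np.concatenate([[0.0], np.asarray(knots)]), np.inf)
            Tref = arr_T if which == "lo" else arr_Tn
            cache[key] = np.minimum(Tref[:, None], edges[None, :])
        return cache[key]

    def _cumhaz_at(self, params, a_s, scale_log, which, arr_T, arr_Tn, cache):
        """Cumulative hazard at T ("lo") or at the next visit ("hi"),
        vectorized over nodes: differences of e^{a_s c} at interval edges
        clipped to the endpoint, with the linear limit when a_s ~ 0."""
        c = self._clipped_edges(params.knots, which, arr_T, arr_Tn, cache)
        E = np.exp(np.clip(a_s[:, :, None] * c[:, None, :], -700.0, 700.0))
        with np.errstate(divide="ignore", invalid="ignore"):
            seg = np.diff(E, axis=2) / a_s[:, :, None]
        lin = np.diff(c, axis=1)[:, None, :]
        small = (np.abs(a_s) * self.t_max < 1e-8)[:, :, None]
        seg = np.where(small, np.broadcast_to(lin, seg.shape), seg)
        return (seg @ params.xi) * np.exp(np.clip(scale_log, -700.0, 700.0))

    def _log_dropout(self, params: SPMParams, b_nodes, arm, T, T_next, event,
                     cache):
        """(m, Kq) log-contribution of the dropout datum at the nodes.

        ``interval`` form: events are interval-censored between the last
        available and the first missed visit, P = S(t_D) - S(t_{D+1});
        ``exact`` form: density at the recorded time,
        hazard(T)^event * exp(-Lambda(T)).
        """
        lmm = params.lmm
        arm = arm[:, None]
        level = lmm.beta0 + b_nodes[..., 0]
        slope = lmm.beta1 + lmm.beta2 * arm + b_nodes[..., 1]
        a_s = params.alpha * slope
        scale_log = params.gamma * arm + params.alpha * level
        cum_lo = self._cumhaz_at(params, a_s, scale_log, "lo", T, T_next, cache)
        ev = event[:, None]
        if self.form == "interval":
            if not event.any():
                return -cum_lo
            cum_hi = self._cumhaz_at(params, a_s, scale_log, "hi", T, T_next,
                                     cache)
            delta = np.maximum(cum_hi - cum_lo, 1e-300)
            with np.errstate(divide="ignore"):
                log_pdrop = np.log(-np.expm1(-delta))
            return -cum_lo + ev * log_pdrop
        q_at = interval_index(params.knots, T)
        log_haz = np.log(params.xi[q_at])[:, None] + scale_log + a_s * T[:, None]
        return ev * log_haz - cum_lo

    def _posterior_nodes(self, lmm: LMMParams):
        """Marginal-normal total and posterior-centered nodes; cached on
        (beta, G, sigma2) so perturbations of the hazard parameters alone
        (finite-difference gradients) skip the group loop."""
        G, s2, beta = lmm.G, lmm.sigma2, lmm.beta
        key = (beta.tobytes(), G.tobytes(), s2)
        if self._post_cache_key == key:
            return self._post_cache_val
        if np.linalg.eigvalsh(G).min() <= 0:
            raise np.linalg.LinAlgError("G must be positive definite")
        total = 0.0
        # marginal density and posterior nodes per availability group; the
        # node-heavy survival factor is then evaluated once over all subjects
        b_nodes = np.empty((self.n, self.Kq, 2))
        for g in self.groups:
            Z = g["Z"]
            d = Z.shape[0]
            V = Z @ G @ Z.T + s2 * np.eye(d)
            cf = np.linalg.cholesky(V)
            logdet = 2.0 * np.log(np.diag(cf)).sum()
            Vinv = np.linalg.inv(V)
            R = g["Y"] - g["X"] @ beta                            # (m, d)
            qf = np.einsum("md,de,me->m", R, Vinv, R)
            total += -0.5 * (g["Y"].shape[0] * (d * _LOG2PI + logdet) + qf.sum())
            # exact posterior of b given this group's observations
            P = G @ Z.T @ Vinv                                    # (2, d)
            modes = R @ P.T                                       # (m, 2)
            B = G - P @ Z @ G
            B = 0.5 * (B + B.T) + 1e-12 * np.eye(2)
            LB = np.linalg.cholesky(B)
            b_nodes[g["idx"]] = (modes[:, None, :]
                                 + np.sqrt(2.0) * (self.U @ LB.T)[None, :, :])
        self._post_cache_key = key
        self._post_cache_val = (total, b_nodes)
        return self._post_cache_val

    def _loglik_adaptive(self, params: SPMParams) -> float:
        total, b_nodes = self._posterior_nodes(params.lmm)
        logw = np.log(self.W) - np.log(np.pi)
        log_surv = self._log_dropout(params, b_nodes, self.arm, self.T,
                                     self.T_next, self.event, self.edge_cache)
        total += special.logsumexp(log_surv + logw[None, :], axis=1).sum()
        return float(total)

    def _loglik_fixed(self, params: SPMParams) -> float:
        lmm = params.lmm
        G, s2, beta = lmm.G, lmm.sigma2, lmm.beta
        sign, logdetG = np.linalg.slogdet(G)
        if sign <= 0:
            raise np.linalg.LinAlgError("G must be positive definite")
        Ginv = np.linalg.inv(G)
        modes, L = self.centering
        total = 0.0
        for g in self.groups:
            idx = g["idx"]
            Lg = L[idx]
            b_nodes = (modes[idx][:, None, :]
                       + np.sqrt(2.0) * np.einsum("mij,kj->mki", Lg, self.U))
            logdetL = np.log(Lg[:, 0, 0]) + np.log(Lg[:, 1, 1])
            logw = (np.log(2.0) + logdetL[:, None]
                    + (np.log(self.W) + (self.U ** 2).sum(axis=1))[None, :])
            r = (g["Y"][:, None, :] - (g["X"] @ beta)[:, None, :]
                 - b_nodes @ g["Z"].T)                            # (m, Kq, d)
            d = g["Z"].shape[0]
            log_long = (-0.5 * d * (_LOG2PI + np.log(s2))
                        - (r * r).sum(axis=2) / (2.0 * s2))
            b0, b1 = b_nodes[..., 0], b_nodes[..., 1]
            quad_b = (b0 * (Ginv[0, 0] * b0 + Ginv[0, 1] * b1)
                      + b1 * (Ginv[1, 0] * b0 + Ginv[1, 1] * b1))
            log_prior = -_LOG2PI - 0.5 * logdetG - 0.5 * quad_b
            log_surv = self._log_dropout(params, b_nodes, g["arm"], g["T"],
                                         g["T_next"], g["event"],
                                         g["edge_cache"])
            total += special.logsumexp(
                log_long + log_surv + log_prior + logw, axis=1).sum()
        return float(total)

    def loglik(self, params: SPMParams) -> float:
        if self.centering is None:
            return self._loglik_adaptive(params)
        return self._loglik_fixed(params)


def _centering_from(params_lmm: LMMParams, dataset: TrialDataset):
    modes, covs = eb_estimates(params_lmm, dataset)
    return modes, covs


def spm_loglik(params: SPMParams, dataset: TrialDataset,
               quad: GHConfig | None = None, form: str = "interval") -> float:
    """Joint log-likelihood; adaptive centering at the posterior implied by
    ``params`` unless the config carries a fixed (pseudo-adaptive) centering.

    ``form="interval"`` (default) treats each dropout as interval-censored
    between the last available and the first missed visit; ``form="exact"``
    evaluates the hazard density at the recorded time (which, with all event
    times on the visit grid, has an unbounded likelihood in alpha and is
    retained for diagnostics and the alpha = 0 decoupling identity only)."""
    quad = quad or GHConfig()
    ctx = _SPMContext(dataset, quad, quad.centering, form=form)
    return ctx.loglik(params)


def pseudo_adaptive_config(dataset: TrialDataset, n_nodes: int = 9) -> GHConfig:
    """Quadrature config with nodes fixed at the empirical-Bayes posteriors
    of a preliminary REML mixed-model fit (the pseudo-adaptive scheme)."""
    pre = fit_lmm(dataset, method="REML")
    return GHConfig(n_nodes=n_nodes,
                    centering=_centering_from(pre.params, dataset))


def _pack(beta, theta, gamma, alpha, log_xi):
    return np.concatenate([beta, theta, [gamma, alpha], log_xi])


def _unpack(x, knots):
    beta = x[:3]
    _, G, s2 = _marginal.chol_from_theta(x[3:7])
    lmm = LMMParams(*beta, G=G, sigma2=s2)
    gamma, alpha = float(x[7]), float(x[8])
    xi = np.exp(x[9:])
    return SPMParams(lmm=lmm, gamma=gamma, alpha=alpha, xi=xi, knots=knots)


def fit_spm(dataset: TrialDataset, quad: GHConfig | None = None,
            knots=DEFAULT_KNOTS, form: str = "interval",
            compute_se: bool = True, maxiter: int = 400) -> SPMFit:
    """Maximize the joint likelihood.

    Initialization: REML LMM for the trajectory part and a
    piecewise-exponential fit with alpha = 0 for the hazard part.  The
    random-effects integral uses adaptively centered Gauss-Hermite nodes by
    default (see :class:`_SPMContext`); pass a config from
    :func:`pseudo_adaptive_config` for fixed-node quadrature.  Standard
    errors come from the numerically differentiated observed information
    (baseline levels on the log scale); inversion failure sets
    ``hessian_ok = False``.
    """
    quad = quad or GHConfig()
    dt = dropout_times(dataset)
    n_events = int(dt.event.sum())
    pre = fit_lmm(dataset, method="REML")
    if n_events == 0:
        _LOG.warning("no dropout events: the survival part is degenerate and "
                     "the fit reduces to the linear mixed model")
        ml = fit_lmm(dataset, method="ML")
        Q = len(knots) + 1
        params = SPMParams(lmm=ml.params, gamma=0.0, alpha=0.0,
                           xi=np.full(Q, 1e-8), knots=tuple(knots))
        return SPMFit(params=params, se_beta=ml.se, se_gamma=np.nan,
                      se_alpha=np.nan, se_log_xi=np.full(Q, np.nan), vcov=None,
                      loglik=ml.loglik, converged=ml.converged,
                      hessian_ok=False, quad_nodes=quad.n_nodes,
                      n_events=0, n_iter=ml.n_iter)

    ctx = _SPMContext(dataset, quad, quad.centering, form=form)
    xi0, gamma0 = fit_piecewise_exponential(dt.T, dt.event, dataset.arm, knots)
    x0 = _pack(pre.params.beta,
               _marginal.theta_from(pre.params.G, pre.params.sigma2),
               gamma0, 0.0, np.log(np.clip(xi0, 1e-8, None)))

    def negll(x):
        try:
            val = -ctx.loglik(_unpack(x, tuple(knots)))
            return val if np.isfinite(val) else 1e12
        except (np.linalg.LinAlgError, ValueError, FloatingPointError):
            return 1e12

    Q = len(knots) + 1
    # rescaled axes: intercept in points, association per point, baseline on
    # the log scale -- magnitudes span four orders otherwise
    scale = np.concatenate([[2.0, 0.5, 0.5], [0.1, 0.5, 0.1, 0.1],
                            [0.2, 0.01], np.full(Q, 0.5)])
    bounds = ([(None, None)] * 3 + list(_marginal.THETA_BOUNDS)
              + [(-10.0, 10.0), (-2.0, 2.0)] + [(-30.0, 5.0)] * Q)
    bounds_z = [(lo / s if lo is not None else None,
                 hi / s if hi is not None else None)
                for (lo, hi), s in zip(bounds, scale)]
    res = optimize.minimize(lambda z: negll(z * scale), x0 / scale,
                            method="L-BFGS-B", bounds=bounds_z,
                            options={"ftol": 1e-10, "gtol": 1e-6,
                                     "maxiter": maxiter})
    res.x = res.x * scale
    params = _unpack(res.x, tuple(knots))

    vcov = None
    hessian_ok = False
    se_beta = np.full(3, np.nan)
    se_gamma = se_alpha = np.nan
    se_log_xi = np.full(Q, np.nan)
    if compute_se:
        H = _numdiff.hessian(negll, res.x)
        vcov, hessian_ok = _numdiff.safe_inverse(H)
        if hessian_ok:
            se = np.sqrt(np.diag(vcov))
            se_beta = se[:3]
            se_gamma, se_alpha = float(se[7]), float(se[8])
            se_log_xi = se[9:]
        else:
            _LOG.warning("observed information not invertible; no SPM standard errors")
    return SPMFit(params=params, se_beta=se_beta, se_gamma=se_gamma,
                  se_alpha=se_alpha, se_log_xi=se_log_xi, vcov=vcov,
                  loglik=float(-res.fun), converged=bool(res.success),
                  hessian_ok=hessian_ok, quad_nodes=quad.n_nodes,
                  n_events=n_events, n_iter=int(res.nit))


def dropout_hazard_ratio(alpha, delta, alpha_ci=None):
    """Hazard ratio exp(alpha * delta) for a score change of ``delta`` points;
    CI endpoints are the same transform of alpha's CI endpoints (sorted)."""
    hr = float(np.exp(alpha * delta))
    if alpha_ci is None:
        return hr
    lo, hi = sorted(float(np.exp(a * delta)) for a in alpha_ci)
    return hr, (lo, hi)
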