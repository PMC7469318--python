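"""Diggle-Kenward selection model for monotone informative dropout.

The joint law of scores and dropout factorizes as
[marginal scores] x [dropout | scores]; the dropout hazard at visit j+1 is
logistic in the last observed score and the current, possibly unobserved,
score:

    logit P(D = j | D >= j, y_j, y_{j+1}) = psi0 + psi1 y_j + psi2 y_{j+1}

A non-zero psi1 points to MAR, a non-zero psi2 to MNAR (informative)
dropout.  Each dropout's likelihood contribution integrates the hazard over
the Gaussian conditional law of the unobserved current score given the
observed history; the integral is evaluated by Gauss-Hermite quadrature on
the standardized conditional scale (the integrand is logistic x Gaussian),
with an adaptive Gauss-Kronrod rule available as a cross-check.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import integrate, linalg, optimize, special, stats

from . import _marginal, _numdiff
from .core_data import TrialDataset
from .lmm import LMMParams, design_matrices, fit_lmm

_LOG = logging.getLogger(__name__)
_LOG2PI = np.log(2.0 * np.pi)

_PSI_BOUNDS = ((-20.0, 20.0), (-5.0, 5.0), (-5.0, 5.0))


@dataclasses.dataclass
class DKParams:
    """Dropout-logistic coefficients; psi1/psi2 are per raw score point."""

    psi0: float
    psi1: float
    psi2: float

    def __post_init__(self):
        if not np.isfinite([self.psi0, self.psi1, self.psi2]).all():
            raise ValueError("dropout parameters must be finite")

    @property
    def psi(self) -> np.ndarray:
        return np.array([self.psi0, self.psi1, self.psi2])


@dataclasses.dataclass
class SMFit:
    lmm: LMMParams
    dk: DKParams
    se_beta: np.ndarray
    se_psi: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    hessian_ok: bool
    n_iter: int = 0


@dataclasses.dataclass(frozen=True)
class QuadConfig:
    """Integration rule for the dropout-visit integral."""

    n_nodes: int = 30
    method: str = "gauss-hermite"  # or "kronrod"

    def nodes(self):
        x, w = special.roots_hermite(self.n_nodes)
        return x, w / np.sqrt(np.pi)


def dk_hazard(dk: DKParams, y_prev, y_curr):
    """Visit-wise dropout probability, inverse-logit of the linear index."""
    eta = dk.psi0 + dk.psi1 * np.asarray(y_prev, float) + dk.psi2 * np.asarray(y_curr, float)
    return special.expit(eta)


def conditional_next_score(lmm: LMMParams, arm, observed, times, next_time):
    """Gaussian conditional moments of the score at ``next_time`` given the
    observed history, under the joint-normal trajectory model."""
    observed = np.asarray(observed, dtype=float)
    times = np.asarray(times, dtype=float)
    if observed.size < 1:
        raise ValueError("need at least one observed score")
    all_t = np.append(times, next_time)
    X, Z = design_matrices(arm, all_t)
    mu = X @ lmm.beta
    V = Z @ lmm.G @ Z.T + lmm.sigma2 * np.eye(all_t.size)
    d = times.size
    V11 = V[:d, :d]
    c = V[:d, d]
    try:
        cf = linalg.cho_factor(V11, lower=True)
    except np.linalg.LinAlgError:
        raise np.linalg.LinAlgError("singular observed-block covariance")
    w = linalg.cho_solve(cf, c)
    mean = float(mu[d] + w @ (observed - mu[:d]))
    var = float(V[d, d] - c @ w)
    return mean, max(var, 0.0)


def _require_monotone(dataset: TrialDataset):
    if not dataset.is_monotone():
        raise ValueError(
            "dataset has intermittent gaps; the selection model is defined "
            "for monotone dropout -- apply core_data.monotonize first"
        )


class _SMContext:
    """Precomputed per-D grouping for fast joint-likelihood evaluation."""

    def __init__(self, dataset: TrialDataset):
        _require_monotone(dataset)
        self.J = dataset.schedule.J
        t = dataset.schedule.times_array()
        D = dataset.dropout_index
        self.n_dropouts = int((D < self.J).sum())
        self.groups = []
        for d in range(1, self.J + 1):
            idx = np.flatnonzero(D == d)
            if idx.size == 0:
                continue
            Y = dataset.scores[np.ix_(idx, np.arange(d))]
            arm = dataset.arm[idx].astype(float)
            tt = t[:d]
            X = np.empty((idx.size, d, 3))
            X[:, :, 0] = 1.0
            X[:, :, 1] = tt[None, :]
            X[:, :, 2] = arm[:, None] * tt[None, :]
            g = {"d": d, "Y": Y, "arm": arm, "times": tt, "X": X,
                 "Z": np.column_stack([np.ones(d), tt]),
                 "eta_pairs": (Y[:, :-1], Y[:, 1:]) if d >= 2 else None,
                 "next_time": t[d] if d < self.J else None}
            if g["next_time"] is not None:
                tn = g["next_time"]
                g["zn"] = np.array([1.0, tn])
                g["x_next"] = np.column_stack(
                    [np.ones(idx.size), np.full(idx.size, tn), arm * tn])
            self.groups.append(g)
        # global concatenations: survival pairs over every subject, and the
        # dropout-integral slots over every non-completer
        prev, curr = [], []
        y_last, slices = [], []
        pos = 0
        for g in self.groups:
            if g["eta_pairs"] is not None:
                prev.append(g["eta_pairs"][0].ravel())
                curr.append(g["eta_pairs"][1].ravel())
            if g["next_time"] is not None:
                m = g["Y"].shape[0]
                g["slot"] = slice(pos, pos + m)
                y_last.append(g["Y"][:, -1])
                pos += m
        self.pairs_prev = (np.concatenate(prev) if prev else np.empty(0))
        self.pairs_curr = (np.concatenate(curr) if curr else np.empty(0))
        self.y_last = (np.concatenate(y_last) if y_last else np.empty(0))
        self.n_drop_slots = pos
        self._cache_key = None

    def _trajectory_part(self, lmm: LMMParams):
        """Marginal-normal total plus conditional moments of the unobserved
        next score; cached on (beta, G, sigma2) so that finite-difference
        perturbations of psi alone reuse it."""
        beta, G, s2 = lmm.beta, lmm.G, lmm.sigma2
        key = (beta.tobytes(), G.tobytes(), s2)
        if self._cache_key == key:
            return self._cache_val
        if np.linalg.eigvalsh(G).min() < -1e-10:
            raise ValueError("G must be positive semi-definite")
        total = 0.0
        m_cond = np.empty(self.n_drop_slots)
        sd_cond = np.empty(self.n_drop_slots)
        for g in self.groups:
            d, Y, Z = g["d"], g["Y"], g["Z"]
            V = Z @ G @ Z.T + s2 * np.eye(d)
            cf = linalg.cho_factor(V, lower=True)
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            Vinv = linalg.cho_solve(cf, np.eye(d))
            R = Y - g["X"] @ beta
            qf = np.einsum("md,de,me->m", R, Vinv, R)
            total += -0.5 * (Y.shape[0] * (d * _LOG2PI + logdet) + qf.sum())
            if g["next_time"] is not None:
                zn = g["zn"]
                c = Z @ G @ zn                      # Cov(history, next)
                w = Vinv @ c
                m_cond[g["slot"]] = g["x_next"] @ beta + R @ w
                v = max(float(zn @ G @ zn + s2 - c @ w), 1e-12)
                sd_cond[g["slot"]] = np.sqrt(v)
        self._cache_key = key
        self._cache_val = (total, m_cond, sd_cond)
        return self._cache_val

    def loglik(self, lmm: LMMParams, dk: DKParams, quad: QuadConfig) -> float:
        total, m_cond, sd_cond = self._trajectory_part(lmm)
        # survival factors over observed consecutive pairs
        if self.pairs_prev.size:
            eta = dk.psi0 + dk.psi1 * self.pairs_prev + dk.psi2 * self.pairs_curr
            total = total - np.logaddexp(0.0, eta).sum()
        # dropout-visit integral over the conditional law of the next score
        if self.n_drop_slots:
            if quad.method == "kronrod":
                for yd, mc, sc in zip(self.y_last, m_cond, sd_cond):
                    total += np.log(_kronrod_integral(dk, yd, mc, sc ** 2))
            else:
                xk, wk = quad.nodes()
                ygrid = (m_cond[:, None]
                         + np.sqrt(2.0) * sd_cond[:, None] * xk[None, :])
                eta = dk.psi0 + dk.psi1 * self.y_last[:, None] + dk.psi2 * ygrid
                logp = -np.logaddexp(0.0, -eta)     # log expit
                total += special.logsumexp(logp + np.log(wk)[None, :],
                                           axis=1).sum()
        return float(total)


def _kronrod_integral(dk: DKParams, y_prev, mean, var):
    sd = np.sqrt(var)
    val, _ = integrate.quad(
        lambda y: special.expit(dk.psi0 + dk.psi1 * y_prev + dk.psi2 * y)
        * stats.norm.pdf(y, mean, sd),
        mean - 10 * sd, mean + 10 * sd, limit=200,
    )
    return val


def sm_loglik(lmm: LMMParams, dk: DKParams, dataset: TrialDataset,
              quad: QuadConfig | None = None) -> float:
    """Joint log-likelihood of scores and dropout over all subjects."""
    return _SMContext(dataset).loglik(lmm, dk, quad or QuadConfig())


def _pack(beta, theta, psi):
    return np.concatenate([beta, theta, psi])


def _unpack(x):
    beta = x[:3]
    _, G, s2 = _marginal.chol_from_theta(x[3:7])
    lmm = LMMParams(*beta, G=G, sigma2=s2)
    dk = DKParams(*x[7:10])
    return lmm, dk


def fit_sm(dataset: TrialDataset, init=None, quad: QuadConfig | None = None,
           compute_se: bool = True, maxiter: int = 400) -> SMFit:
    """Maximize the joint likelihood over all 10 parameters.

    Default initialization: REML LMM fit for the trajectory part plus an
    MCAR logistic fit (psi1 = psi2 = 0, psi0 at the crude per-opportunity
    dropout rate).  Standard errors come from the numerically differentiated
    observed information; if that matrix cannot be inverted the fit is
    returned with ``hessian_ok = False`` and a warning, not a failure.
    """
    quad = quad or QuadConfig()
    ctx = _SMContext(dataset)
    if ctx.n_dropouts == 0:
        _LOG.warning("no dropouts: psi1/psi2 are unidentified beyond psi0")

    if init is None:
        lmm0 = fit_lmm(dataset, method="REML").params
        D = dataset.dropout_index
        J = dataset.schedule.J
        opportunities = int(np.minimum(D, J - 1).sum())
        p_hat = np.clip(ctx.n_dropouts / max(opportunities, 1), 1e-6, 1 - 1e-6)
        dk0 = DKParams(float(special.logit(p_hat)), 0.0, 0.0)
    else:
        lmm0, dk0 = init
    x0 = _pack(lmm0.beta, _marginal.theta_from(lmm0.G, lmm0.sigma2), dk0.psi)

    def negll(x):
        try:
            lmm, dk = _unpack(x)
            val = -ctx.loglik(lmm, dk, quad)
            return val if np.isfinite(val) else 1e12
        except (np.linalg.LinAlgError, ValueError):
            return 1e12

    # typical parameter magnitudes differ by four orders (intercept in points
    # vs psi per point); optimize on a rescaled axis system
    scale = np.array([2.0, 0.5, 0.5, 0.1, 0.5, 0.1, 0.1, 0.5, 0.01, 0.01])
    bounds = ([(None, None)] * 3 + list(_marginal.THETA_BOUNDS)
              + list(_PSI_BOUNDS))
    bounds_z = [(lo / s if lo is not None else None,
                 hi / s if hi is not None else None)
                for (lo, hi), s in zip(bounds, scale)]
    opts = {"ftol": 1e-10, "gtol": 1e-6, "maxiter": maxiter}
    res = optimize.minimize(lambda z: negll(z * scale), x0 / scale,
                            method="L-BFGS-B", bounds=bounds_z, options=opts)
    if not res.success:
        res2 = optimize.minimize(
            lambda z: negll(z * scale),
            res.x + np.random.default_rng(0).normal(0, 1e-2, res.x.size),
            method="L-BFGS-B", bounds=bounds_z, options=opts)
        if res2.fun <= res.fun:
            res = res2
    res.x = res.x * scale
    lmm_hat, dk_hat = _unpack(res.x)

    vcov = None
    hessian_ok = False
    se_beta = np.full(3, np.nan)
    se_psi = np.full(3, np.nan)
    if compute_se:
        H = _numdiff.hessian(negll, res.x)
        vcov, hessian_ok = _numdiff.safe_inverse(H)
        if hessian_ok:
            se = np.sqrt(np.diag(vcov))
            se_beta, se_psi = se[:3], se[7:10]
        else:
            _LOG.warning("observed information not invertible; no SM standard errors")
    return SMFit(lmm=lmm_hat, dk=dk_hat, se_beta=se_beta, se_psi=se_psi,
                 vcov=vcov, loglik=float(-res.fun), converged=bool(res.success),
                 hessian_ok=hessian_ok, n_iter=int(res.nit))
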