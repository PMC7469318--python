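"""Random-coefficients linear mixed model for HRQoL score trajectories.

The mean score at planned time t for a subject in arm a is

    mu(t) = beta0 + beta1 t + beta2 (a * t)

so beta1 is the control-arm slope (points/month) and beta2 the difference
between the experimental and control slopes; randomization justifies a
common baseline, so no main arm effect enters.  Subject-level deviations
are a random intercept and slope b = (b0, b1) ~ N(0, G), with white-noise
residuals of variance sigma^2.  Likelihood inference on the observed data
is valid under MAR; this model is both the reference fit and the
longitudinal sub-model shared by the three MNAR approaches.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import linalg

from . import _marginal
from .core_data import TrialDataset

_LOG = logging.getLogger(__name__)


@dataclasses.dataclass
class LMMParams:
    """Fixed effects, random-effects covariance G (2x2), residual variance."""

    beta0: float
    beta1: float
    beta2: float
    G: np.ndarray
    sigma2: float

    def __post_init__(self):
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (2, 2):
            raise ValueError("G must be 2x2")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("G must be symmetric")
        if np.linalg.eigvalsh(self.G).min() < -1e-10:
            raise ValueError("G must be positive semi-definite")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])


@dataclasses.dataclass
class LMMFit:
    params: LMMParams
    se: np.ndarray
    vcov_fixed: np.ndarray
    loglik: float
    method: str
    converged: bool
    theta: np.ndarray = None
    n_iter: int = 0


def design_matrices(arm, times):
    """Fixed and random design rows at planned times: X = [1, t, arm*t]."""
    t = np.asarray(times, dtype=float)
    X = np.column_stack([np.ones_like(t), t, float(arm) * t])
    Z = np.column_stack([np.ones_like(t), t])
    return X, Z


def marginal_moments(params: LMMParams, arm, times):
    """Marginal mean vector and covariance V = Z G Z' + sigma^2 I."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("times must be non-empty")
    X, Z = design_matrices(arm, t)
    mean = X @ params.beta
    cov = Z @ params.G @ Z.T + params.sigma2 * np.eye(t.size)
    return mean, cov


def predict_mean(params: LMMParams, arm, times) -> np.ndarray:
    """Population mean trajectory at the given times (one arm)."""
    X, _ = design_matrices(arm, np.asarray(times, dtype=float))
    return X @ params.beta


def _full_design_rows(dataset: TrialDataset) -> np.ndarray:
    t = dataset.schedule.times_array()
    n, J = dataset.n_subjects, dataset.schedule.J
    X = np.empty((n, J, 3))
    X[:, :, 0] = 1.0
    X[:, :, 1] = t[None, :]
    X[:, :, 2] = dataset.arm[:, None] * t[None, :]
    return X


def _problem(dataset: TrialDataset) -> _marginal.MarginalProblem:
    groups, _ = _marginal.build_groups(
        dataset.scores, dataset.schedule.times_array(), _full_design_rows(dataset)
    )
    return _marginal.MarginalProblem(groups)


def lmm_loglik(params: LMMParams, dataset: TrialDataset, method: str = "ML") -> float:
    """Observed-data log-likelihood; each subject contributes its available
    visits only.  REML ignores the supplied fixed effects (it is a likelihood
    of error contrasts) and includes the fixed-effects projection term."""
    prob = _problem(dataset)
    return prob.loglik_at(params.beta, params.G, params.sigma2, method=method)


def fit_lmm(dataset: TrialDataset, method: str = "REML",
            start: LMMParams | None = None) -> LMMFit:
    """Fit by profiled (RE)ML over a log-Cholesky variance parametrization.

    The returned fixed effects are the GLS solution at the estimated
    variance components by construction; Wald inference uses the normal
    reference distribution.
    """
    if dataset.n_subjects < 2:
        raise ValueError("need at least two subjects")
    obs_times = dataset.schedule.times_array()[
        np.flatnonzero(dataset.observed.any(axis=0))
    ]
    if np.unique(obs_times).size < 2:
        raise ValueError("degenerate design: fewer than two distinct times")
    prob = _problem(dataset)
    start_theta = None
    if start is not None:
        start_theta = _marginal.theta_from(start.G, start.sigma2)
    ef = prob.fit(method=method, start=start_theta)
    if not ef.converged:
        _LOG.warning("LMM optimizer did not report convergence: %s", ef.message)
    _, G, s2 = _marginal.chol_from_theta(ef.theta)
    params = LMMParams(*ef.beta, G=G, sigma2=s2)
    return LMMFit(params=params, se=np.sqrt(np.diag(ef.vcov_beta)),
                  vcov_fixed=ef.vcov_beta, loglik=ef.loglik, method=method,
                  converged=ef.converged, theta=ef.theta, n_iter=ef.n_iter)


def eb_estimates(params: LMMParams, dataset: TrialDataset):
    """Empirical-Bayes posterior modes and covariances of b per subject.

    For Gaussian models the posterior of b given y is normal with
    cov B = (Z'Z/sigma^2 + G^-1)^-1 and mean B Z'(y - X beta)/sigma^2.
    Used to center the pseudo-adaptive quadrature of the joint model.
    """
    t_all = dataset.schedule.times_array()
    Ginv = np.linalg.inv(params.G + 1e-12 * np.eye(2))
    n = dataset.n_subjects
    modes = np.zeros((n, 2))
    covs = np.zeros((n, 2, 2))
    obs = dataset.observed
    for i in range(n):
        idx = np.flatnonzero(obs[i])
        tt = t_all[idx]
        X, Z = design_matrices(dataset.arm[i], tt)
        r = dataset.scores[i, idx] - X @ params.beta
        B = np.linalg.inv(Z.T @ Z / params.sigma2 + Ginv)
        modes[i] = B @ (Z.T @ r) / params.sigma2
        covs[i] = B
    return modes, covs
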