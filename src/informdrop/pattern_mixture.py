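"""Pattern-mixture model: dropout patterns, stratified trajectories, and
delta-method marginalization.

The joint law factorizes as [dropout pattern] x [scores | pattern].  Subjects
are grouped into K patterns by their dropout index D; pattern membership is
multinomial with probabilities estimated by the sample proportions pi_k.
Within each pattern the trajectory model keeps the random-coefficients
structure but with pattern-specific fixed effects (beta0^k, beta1^k,
beta2^k).  Marginal effects are the pi-weighted sums

    beta_l = sum_k beta_l^k pi_k,   l = 0, 1, 2

whose straight-line predictions implicitly extrapolate each pattern's
trajectory beyond its last visit.  Confidence intervals come from the delta
method treating the effect estimates and the multinomial proportions as
independent (the proportions depend on dropout only; the effects are
estimated conditionally on pattern).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from . import _marginal
from .core_data import TrialDataset

_LOG = logging.getLogger(__name__)
_Z95 = 1.959963984540054


@dataclasses.dataclass(frozen=True)
class PatternScheme:
    """Partition of dropout indices 1..J into K ordered pattern groups."""

    groups: tuple

    def __post_init__(self):
        groups = tuple(tuple(int(d) for d in g) for g in self.groups)
        flat = [d for g in groups for d in g]
        if len(set(flat)) != len(flat):
            raise ValueError("pattern groups must be disjoint")
        if any(len(g) == 0 for g in groups):
            raise ValueError("empty pattern group")
        object.__setattr__(self, "groups", groups)

    @property
    def K(self) -> int:
        return len(self.groups)

    def validate_for(self, J: int):
        flat = sorted(d for g in self.groups for d in g)
        if flat != list(range(1, J + 1)):
            raise ValueError(
                f"pattern groups must partition dropout indices 1..{J}, got {flat}"
            )

    def label_for(self, D: int) -> int:
        """1-based pattern label for a dropout index."""
        for k, g in enumerate(self.groups, start=1):
            if D in g:
                return k
        raise ValueError(f"dropout index {D} not covered by the scheme")


def default_scheme() -> PatternScheme:
    """Four patterns: drop before V3; last visit V3/V4; V5; V6 or completer."""
    return PatternScheme(((1, 2, 3), (4, 5), (6,), (7, 8)))


@dataclasses.dataclass
class PatternAssignment:
    labels: np.ndarray          # 1-based pattern label per subject
    counts: np.ndarray          # (K,)
    pi: np.ndarray              # (K,)
    cov_pi: np.ndarray          # (K, K) multinomial covariance of pi-hat


def assign_patterns(dataset: TrialDataset, scheme: PatternScheme | None = None
                    ) -> PatternAssignment:
    """Label subjects by pattern; pi_k = n_k / n with multinomial covariance
    (diag(pi) - pi pi') / n."""
    scheme = scheme or default_scheme()
    scheme.validate_for(dataset.schedule.J)
    D = dataset.dropout_index
    labels = np.array([scheme.label_for(int(d)) for d in D])
    K = scheme.K
    counts = np.array([(labels == k).sum() for k in range(1, K + 1)])
    n = dataset.n_subjects
    pi = counts / n
    cov_pi = (np.diag(pi) - np.outer(pi, pi)) / n
    for k in range(K):
        if counts[k] == 0:
            _LOG.warning("pattern %d is empty; it will be dropped at fitting", k + 1)
    return PatternAssignment(labels=labels, counts=counts, pi=pi, cov_pi=cov_pi)


@dataclasses.dataclass
class PMMFit:
    scheme: PatternScheme
    assignment: PatternAssignment
    betas: np.ndarray           # (K, 3) pattern fixed effects (NaN if dropped)
    se_betas: np.ndarray        # (K, 3)
    vcov: np.ndarray            # (3K, 3K) joint covariance, zeros where dropped
    retained: np.ndarray        # bool (K,)
    beta2_zeroed: np.ndarray    # bool (K,): interaction dropped (single-arm pattern)
    G: np.ndarray | list
    sigma2: float | list
    loglik: float
    method: str
    variance_mode: str
    converged: bool
    arm: np.ndarray = None      # per-subject arm, kept for arm-specific weights


@dataclasses.dataclass
class MarginalEffects:
    """pi-weighted effects with delta-method SEs; CI = est +/- 1.96 SE."""

    estimate: np.ndarray        # (3,)
    se: np.ndarray              # (3,)
    ci_low: np.ndarray
    ci_high: np.ndarray
    weights: str


def _pattern_design(times, arm, label, K, col_active):
    """Design row block: columns [k, l] for pattern k, effect l in (1, t, arm*t)."""
    t = np.asarray(times, dtype=float)
    cols = []
    for k in range(1, K + 1):
        base = np.zeros((t.size, 3))
        if k == label:
            base[:, 0] = 1.0
            base[:, 1] = t
            base[:, 2] = float(arm) * t
        cols.append(base)
    X = np.concatenate(cols, axis=1)
    return X[:, col_active]


def fit_pmm(dataset: TrialDataset, scheme: PatternScheme | None = None,
            variance_mode: str = "shared", method: str = "REML",
            start: tuple | None = None) -> PMMFit:
    """Fit the pattern LMM.

    ``shared``: one model with pattern-indexed fixed effects and common
    (G, sigma^2) -- a single LMM with pattern indicator interactions.
    ``start`` is an optional (G, sigma2) warm start for the variance
    components (useful for bootstrap loops).
    ``stratified``: an independent LMM per pattern; the joint covariance is
    block-diagonal.  Patterns with fewer than two subjects are dropped with
    a warning (proportions renormalized at marginalization); a pattern whose
    subjects are all in one arm has its interaction column dropped and
    beta2^k treated as 0, with a prominent warning.
    """
    scheme = scheme or default_scheme()
    assignment = assign_patterns(dataset, scheme)
    K = scheme.K
    retained = assignment.counts >= 2
    if not retained.any():
        raise ValueError("no pattern with at least two subjects")
    for k in np.flatnonzero(~retained):
        if assignment.counts[k] > 0:
            _LOG.warning("pattern %d has < 2 subjects; dropped from the fit", k + 1)

    beta2_zeroed = np.zeros(K, dtype=bool)
    for k in np.flatnonzero(retained):
        arms_k = dataset.arm[assignment.labels == k + 1]
        if arms_k.min() == arms_k.max():
            beta2_zeroed[k] = True
            _LOG.warning(
                "pattern %d contains a single arm; its arm-by-time interaction "
                "is dropped and treated as 0 in marginalization", k + 1
            )

    # active columns in the full (K, 3) layout
    active = np.zeros((K, 3), dtype=bool)
    for k in range(K):
        if retained[k]:
            active[k] = [True, True, not beta2_zeroed[k]]
    col_active = active.reshape(-1)

    betas = np.full((K, 3), np.nan)
    se_betas = np.full((K, 3), np.nan)
    vcov = np.zeros((3 * K, 3 * K))
    t_all = dataset.schedule.times_array()

    if variance_mode == "shared":
        n, J = dataset.n_subjects, dataset.schedule.J
        keep = retained[assignment.labels - 1]
        X_rows = np.zeros((n, J, 3 * K))
        for k in range(K):
            in_k = assignment.labels == k + 1
            X_rows[in_k, :, 3 * k] = 1.0
            X_rows[in_k, :, 3 * k + 1] = t_all[None, :]
            X_rows[in_k, :, 3 * k + 2] = (dataset.arm[in_k, None]
                                          * t_all[None, :])
        X_rows = X_rows[:, :, col_active]
        groups, _ = _marginal.build_groups(
            dataset.scores[keep], t_all, X_rows[keep]
        )
        prob = _marginal.MarginalProblem(groups)
        start_theta = (_marginal.theta_from(*start) if start is not None
                       else None)
        ef = prob.fit(method=method, start=start_theta)
        full_beta = np.zeros(3 * K)
        full_beta[col_active] = ef.beta
        betas = full_beta.reshape(K, 3)
        betas[~retained] = np.nan
        vcov[np.ix_(col_active, col_active)] = ef.vcov_beta
        se_betas = np.sqrt(np.diag(vcov)).reshape(K, 3)
        se_betas[~retained] = np.nan
        _, G, s2 = _marginal.chol_from_theta(ef.theta)
        loglik, converged = ef.loglik, ef.converged
    elif variance_mode == "stratified":
        G, s2 = [], []
        loglik, converged = 0.0, True
        for k in range(K):
            if not retained[k]:
                G.append(None)
                s2.append(None)
                continue
            sub = dataset.subset(assignment.labels == k + 1)
            X_rows = np.stack([
                _pattern_design(t_all, sub.arm[i], 1, 1,
                                np.array([True, True, not beta2_zeroed[k]]))
                for i in range(sub.n_subjects)
            ])
            groups, _ = _marginal.build_groups(sub.scores, t_all, X_rows)
            prob = _marginal.MarginalProblem(groups)
            ef = prob.fit(method=method)
            effects = np.flatnonzero(active[k])       # prefix of (0, 1, 2)
            betas[k, :] = 0.0
            betas[k, effects] = ef.beta
            idx = [3 * k + l for l in effects]
            vcov[np.ix_(idx, idx)] = ef.vcov_beta
            se_betas[k] = np.sqrt(np.diag(vcov)[3 * k: 3 * k + 3])
            _, Gk, s2k = _marginal.chol_from_theta(ef.theta)
            G.append(Gk)
            s2.append(s2k)
            loglik += ef.loglik
            converged = converged and ef.converged
    else:
        raise ValueError(f"unknown variance_mode {variance_mode!r}")

    betas = np.where(np.isnan(betas) & np.repeat(retained[:, None], 3, axis=1),
                     0.0, betas)
    betas[retained & beta2_zeroed, 2] = 0.0
    return PMMFit(scheme=scheme, assignment=assignment, betas=betas,
                  se_betas=se_betas, vcov=vcov, retained=retained,
                  beta2_zeroed=beta2_zeroed, G=G, sigma2=s2, loglik=loglik,
                  method=method, variance_mode=variance_mode, converged=converged,
                  arm=dataset.arm.copy())


def _renormalized_pi(fit: PMMFit):
    counts = fit.assignment.counts[fit.retained]
    n = counts.sum()
    pi = counts / n
    cov = (np.diag(pi) - np.outer(pi, pi)) / n
    return pi, cov


def marginalize_pmm(fit: PMMFit, weights: str = "overall") -> MarginalEffects:
    """Combine pattern effects into marginal effects with delta-method SEs.

    ``overall`` uses the pooled pattern proportions for every effect (the
    weighted-sum formula as printed); ``by_arm`` weights each arm's slope by
    that arm's own pattern proportions and takes the interaction as the
    difference of the two weighted slopes.  Var(est) = w' S_beta w +
    beta' S_pi beta with zero cross-term.
    """
    ret = np.flatnonzero(fit.retained)
    Kr = ret.size
    B = fit.betas[ret]                               # (Kr, 3)
    pi, cov_pi = _renormalized_pi(fit)

    def effect_cov(l):
        idx = [3 * k + l for k in ret]
        return fit.vcov[np.ix_(idx, idx)]

    if weights == "overall":
        est = np.array([pi @ B[:, l] for l in range(3)])
        var = np.array([
            pi @ effect_cov(l) @ pi + B[:, l] @ cov_pi @ B[:, l]
            for l in range(3)
        ])
    elif weights == "by_arm":
        labels = fit.assignment.labels
        arm = _arm_of(fit)
        pis, covs = [], []
        for a in (0, 1):
            counts = np.array([((labels == k + 1) & (arm == a)).sum() for k in ret])
            n_a = counts.sum()
            if n_a == 0:
                raise ValueError(f"no subjects in arm {a}")
            p = counts / n_a
            pis.append(p)
            covs.append((np.diag(p) - np.outer(p, p)) / n_a)
        p0, p1 = pis
        c0, c1 = covs
        slope1 = B[:, 1] + B[:, 2]                   # experimental-arm slopes
        cov11 = effect_cov(1)
        idx1 = [3 * k + 1 for k in ret]
        idx2 = [3 * k + 2 for k in ret]
        cov_s1 = (fit.vcov[np.ix_(idx1, idx1)] + fit.vcov[np.ix_(idx2, idx2)]
                  + fit.vcov[np.ix_(idx1, idx2)] + fit.vcov[np.ix_(idx2, idx1)])
        cov_s1_b1 = fit.vcov[np.ix_(idx1, idx1)] + fit.vcov[np.ix_(idx2, idx1)]
        est0 = pi @ B[:, 0]
        est_b1 = p0 @ B[:, 1]
        est_s1 = p1 @ slope1
        var0 = pi @ effect_cov(0) @ pi + B[:, 0] @ cov_pi @ B[:, 0]
        var_b1 = p0 @ cov11 @ p0 + B[:, 1] @ c0 @ B[:, 1]
        var_s1 = p1 @ cov_s1 @ p1 + slope1 @ c1 @ slope1
        cov_cross = p1 @ cov_s1_b1 @ p0              # estimate covariance only
        est = np.array([est0, est_b1, est_s1 - est_b1])
        var2 = var_s1 + var_b1 - 2.0 * cov_cross
        var = np.array([var0, var_b1, max(var2, 0.0)])
    else:
        raise ValueError(f"unknown weights {weights!r}")

    se = np.sqrt(np.maximum(var, 0.0))
    return MarginalEffects(estimate=est, se=se, ci_low=est - _Z95 * se,
                           ci_high=est + _Z95 * se, weights=weights)


def _arm_of(fit: PMMFit):
    if fit.arm is None:
        raise ValueError("arm-specific weighting needs per-subject arms on the fit")
    return fit.arm


def pattern_trajectories(fit: PMMFit, arm, times) -> np.ndarray:
    """Straight-line pattern trajectories beta0^k + (beta1^k + beta2^k arm) t
    over the full schedule -- extrapolated beyond each pattern's last visit.
    Rows for dropped patterns are NaN."""
    t = np.asarray(times, dtype=float)
    out = np.full((fit.scheme.K, t.size), np.nan)
    for k in range(fit.scheme.K):
        if fit.retained[k]:
            b = fit.betas[k]
            out[k] = b[0] + (b[1] + b[2] * float(arm)) * t
    return out


def marginal_trajectory(fit: PMMFit, arm, times) -> np.ndarray:
    """pi-weighted pointwise combination of the retained pattern curves."""
    pi, _ = _renormalized_pi(fit)
    curves = pattern_trajectories(fit, arm, times)[fit.retained]
    return pi @ curves
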