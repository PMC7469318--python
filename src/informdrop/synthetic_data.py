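"""Synthetic two-arm trial generator with MCAR / MAR / MNAR dropout.

Emulates the structure of a two-arm esophageal-cancer HRQoL trial: ~130
subjects per arm, eight planned visits at months 0, 1.25, 3, 4, 6, 12, 24, 36,
random-intercept/random-slope Gaussian score trajectories, and monotone
dropout generated either visit-by-visit from the logistic dropout hazard
(MCAR when it is constant, MAR when it depends on the last observed score,
MNAR when it depends on the current unobserved score) or in continuous time
from the shared-parameter proportional-hazards model.  Complete trajectories,
random effects, and latent dropout times are retained as ground truth for
parameter-recovery experiments.

Randomness is driven by ``numpy.random.default_rng`` (PCG64), so identical
configuration and seed reproduce byte-identical datasets across platforms.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import special

from .core_data import TrialDataset, VisitSchedule, default_schedule
from .lmm import LMMParams
from .selection_model import DKParams
from .spm import SPMParams, _segment_integral

MECHANISMS = ("mcar", "mar_dk", "mnar_dk", "mnar_spm", "pattern")


def default_truth() -> LMMParams:
    """Generating trajectory parameters: global-health-like magnitudes on the
    0-100 scale (intercept 60 points, control slope 0.5 points/month, slope
    difference -0.13), intercept sd 20 points, slope sd 0.5 points/month,
    residual sd 15 points."""
    return LMMParams(60.0, 0.5, -0.13, G=np.diag([400.0, 0.25]), sigma2=225.0)


def default_spm_hazard() -> dict:
    """Decreasing baseline hazard giving ~95% cumulative dropout by month 36
    for a typical subject under the default association alpha = -0.02."""
    return {
        "gamma": 0.2,
        "alpha": -0.02,
        "xi": np.array([1.2, 1.0, 0.8, 0.5, 0.25, 0.15, 0.12]),
        "knots": (1.25, 3.0, 4.0, 6.0, 12.0, 24.0),
    }


@dataclasses.dataclass
class SimConfig:
    n_per_arm: int = 130
    schedule: VisitSchedule = dataclasses.field(default_factory=default_schedule)
    lmm: LMMParams = dataclasses.field(default_factory=default_truth)
    mechanism: str = "mcar"
    # visit-wise logistic mechanisms; MCAR forces psi1 = psi2 = 0 and
    # MAR forces psi2 = 0 (validated below)
    dk: DKParams = dataclasses.field(default_factory=lambda: DKParams(-0.6, 0.0, 0.0))
    spm_hazard: dict = None
    pattern_pi: np.ndarray = None
    pattern_betas: np.ndarray = None     # (K, 3) pattern-specific fixed effects
    truncate_scores: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "mcar" and (self.dk.psi1 != 0 or self.dk.psi2 != 0):
            raise ValueError("MCAR requires psi1 = psi2 = 0")
        if self.mechanism == "mar_dk" and self.dk.psi2 != 0:
            raise ValueError("MAR requires psi2 = 0 (dropout may depend on "
                             "observed scores only)")
        if self.mechanism == "mnar_spm" and self.spm_hazard is None:
            self.spm_hazard = default_spm_hazard()
        if self.mechanism == "pattern":
            if self.pattern_pi is None or self.pattern_betas is None:
                raise ValueError("pattern mechanism needs pattern_pi and "
                                 "pattern_betas")
            pi = np.asarray(self.pattern_pi, dtype=float)
            if not np.isclose(pi.sum(), 1.0) or (pi < 0).any():
                raise ValueError("pattern_pi must be a probability vector")


@dataclasses.dataclass
class SimulatedTrial:
    dataset: TrialDataset                # observed (post-dropout) view
    complete_scores: np.ndarray          # (n, J), never masked
    random_effects: np.ndarray           # (n, 2)
    config: SimConfig
    latent_dropout: np.ndarray = None    # continuous times (mnar_spm only)
    truncated: bool = False


def _mask_after(complete, D, J):
    scores = complete.copy()
    for i, d in enumerate(D):
        scores[i, d:] = np.nan
    return scores


def simulate_complete(config: SimConfig, rng=None) -> SimulatedTrial:
    """Draw complete trajectories: b ~ N(0, G),
    y_ij = beta0 + beta1 t_j + beta2 arm t_j + b0 + b1 t_j + eps_ij."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = 2 * config.n_per_arm
    t = config.schedule.times_array()
    arm = np.repeat([0, 1], config.n_per_arm)
    p = config.lmm
    b = rng.multivariate_normal(np.zeros(2), p.G, size=n, method="cholesky")
    eps = rng.normal(0.0, np.sqrt(p.sigma2), size=(n, t.size))
    mean = p.beta0 + np.outer(np.ones(n), p.beta1 * t) + np.outer(arm, p.beta2 * t)
    complete = mean + b[:, [0]] + np.outer(b[:, 1], t) + eps
    ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    dataset = TrialDataset(ids, arm, complete.copy(), config.schedule)
    return SimulatedTrial(dataset=dataset, complete_scores=complete,
                          random_effects=b, config=config)


def apply_dk_dropout(trial: SimulatedTrial, dk: DKParams, rng=None,
                     seed: int = 0) -> SimulatedTrial:
    """Sequential visit-by-visit dropout: a subject still at risk before
    visit j+1 drops (D = j) with probability
    expit(psi0 + psi1 y_j + psi2 y_{j+1}) evaluated on its complete scores
    (y_{j+1} is the current, would-be-unobserved value)."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    complete = trial.complete_scores
    n, J = complete.shape
    U = rng.random((n, J - 1))
    D = np.full(n, J)
    at_risk = np.ones(n, dtype=bool)
    for j in range(J - 1):
        eta = dk.psi0 + dk.psi1 * complete[:, j] + dk.psi2 * complete[:, j + 1]
        drop = at_risk & (U[:, j] < special.expit(eta))
        D[drop] = j + 1
        at_risk &= ~drop
    ds = trial.dataset
    masked = TrialDataset(ds.ids, ds.arm, _mask_after(complete, D, J), ds.schedule)
    return SimulatedTrial(dataset=masked, complete_scores=complete,
                          random_effects=trial.random_effects,
                          config=trial.config, latent_dropout=None,
                          truncated=trial.truncated)


def _invert_cumhaz(params: SPMParams, b, arm, target, t_max):
    """Solve Lambda(t) = target by walking the baseline intervals; the
    per-interval inversion is analytic.  Returns a time > t_max when the
    target is not reached before censoring."""
    edges = params.interval_edges()
    slope = params.lmm.beta1 + params.lmm.beta2 * float(arm) + b[1]
    scale = np.exp(params.gamma * float(arm)
                   + params.alpha * (params.lmm.beta0 + b[0]))
    a_s = params.alpha * slope
    acc = 0.0
    for q in range(params.Q):
        lo = edges[q]
        hi = edges[q + 1] if q + 1 < edges.size else np.inf
        hi_eff = min(hi, t_max)
        if hi_eff <= lo:
            break
        inc = params.xi[q] * scale * float(_segment_integral(a_s, lo, hi_eff))
        if acc + inc >= target:
            need = (target - acc) / (params.xi[q] * scale)
            if abs(a_s) * max(hi_eff - lo, 1.0) < 1e-10:
                return lo + need
            inner = np.exp(a_s * lo) + need * a_s
            if inner <= 0:
                return np.inf
            return float(np.log(inner) / a_s)
        acc += inc
    return np.inf


def apply_spm_dropout(trial: SimulatedTrial, hazard: dict | None = None,
                      rng=None, seed: int = 0) -> SimulatedTrial:
    """Continuous-time dropout by inverse-transform sampling of the
    subject-specific cumulative hazard; censoring at the final planned
    visit.  The observed dropout index is the last scheduled visit strictly
    before the drawn time; the latent time is stored."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    hz = hazard or trial.config.spm_hazard or default_spm_hazard()
    ds = trial.dataset
    t = ds.schedule.times_array()
    J = t.size
    t_end = t[-1]
    n = ds.n_subjects
    params = SPMParams(lmm=trial.config.lmm, gamma=hz["gamma"],
                       alpha=hz["alpha"], xi=hz["xi"], knots=hz["knots"])
    targets = -np.log(rng.random(n))
    latent = np.empty(n)
    D = np.empty(n, dtype=int)
    for i in range(n):
        ti = _invert_cumhaz(params, trial.random_effects[i], ds.arm[i],
                            targets[i], t_end)
        if ti > t_end or not np.isfinite(ti):
            latent[i] = t_end
            D[i] = J
        else:
            latent[i] = ti
            D[i] = max(int(np.searchsorted(t, ti, side="left")), 1)
    masked = TrialDataset(ds.ids, ds.arm,
                          _mask_after(trial.complete_scores, D, J), ds.schedule)
    return SimulatedTrial(dataset=masked, complete_scores=trial.complete_scores,
                          random_effects=trial.random_effects,
                          config=trial.config, latent_dropout=latent,
                          truncated=trial.truncated)


def _simulate_pattern(config: SimConfig, rng) -> SimulatedTrial:
    pi = np.asarray(config.pattern_pi, dtype=float)
    betas = np.asarray(config.pattern_betas, dtype=float)
    K = pi.size
    # pattern k covers a contiguous block of dropout indices; reuse the
    # default 4-pattern split when K = 4, else spread 1..J over K blocks
    J = config.schedule.J
    if K == 4 and J == 8:
        blocks = [(1, 2, 3), (4, 5), (6,), (7, 8)]
    else:
        cut = np.array_split(np.arange(1, J + 1), K)
        blocks = [tuple(c) for c in cut]
    n = 2 * config.n_per_arm
    t = config.schedule.times_array()
    arm = np.repeat([0, 1], config.n_per_arm)
    labels = rng.choice(K, size=n, p=pi)
    p = config.lmm
    b = rng.multivariate_normal(np.zeros(2), p.G, size=n, method="cholesky")
    eps = rng.normal(0.0, np.sqrt(p.sigma2), size=(n, J))
    bet = betas[labels]                                   # (n, 3)
    mean = (bet[:, [0]] + np.outer(bet[:, 1], t)
            + bet[:, [2]] * np.outer(arm, t))
    complete = mean + b[:, [0]] + np.outer(b[:, 1], t) + eps
    D = np.array([int(rng.choice(blocks[k])) for k in labels])
    ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    masked = TrialDataset(ids, arm, _mask_after(complete, D, J), config.schedule)
    return SimulatedTrial(dataset=masked, complete_scores=complete,
                          random_effects=b, config=config)


def simulate_trial(config: SimConfig) -> SimulatedTrial:
    """Dispatch on the dropout mechanism; all randomness flows from a single
    PCG64 stream seeded by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    if config.mechanism == "pattern":
        trial = _simulate_pattern(config, rng)
    else:
        trial = simulate_complete(config, rng)
        if config.mechanism in ("mcar", "mar_dk", "mnar_dk"):
            trial = apply_dk_dropout(trial, config.dk, rng)
        elif config.mechanism == "mnar_spm":
            trial = apply_spm_dropout(trial, config.spm_hazard, rng)
    if config.truncate_scores:
        complete = np.clip(trial.complete_scores, 0.0, 100.0)
        obs = trial.dataset.observed
        scores = np.where(obs, complete, np.nan)
        ds = trial.dataset
        trial = SimulatedTrial(
            dataset=TrialDataset(ds.ids, ds.arm, scores, ds.schedule),
            complete_scores=complete, random_effects=trial.random_effects,
            config=config, latent_dropout=trial.latent_dropout, truncated=True)
    return trial


def truth_sidecar(trial: SimulatedTrial):
    """Ground-truth table: complete scores, random effects, latent times."""
    import pandas as pd

    ds = trial.dataset
    cols = {"subject_id": ds.ids, "arm": ds.arm,
            "b0": trial.random_effects[:, 0], "b1": trial.random_effects[:, 1]}
    for j, lab in enumerate(ds.schedule.labels):
        cols[f"complete_{lab}"] = trial.complete_scores[:, j]
    cols["latent_dropout"] = (trial.latent_dropout if trial.latent_dropout
                              is not None else np.full(ds.n_subjects, np.nan))
    return pd.DataFrame(cols)
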