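"""Fit all four models on one dataset and tabulate the comparison.

Produces an estimates table (estimate, 95% Wald CI, two-sided normal
p-value per parameter and model), per-model log-likelihoods and convergence
flags, predicted mean-trajectory curves per arm (plus per-pattern curves
for the pattern-mixture model and the baseline-hazard step curve for the
joint model), and optional figures.  Every number in the exported table is
read off a fit object; the formatter never recomputes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import TrialDataset
from .lmm import LMMFit, fit_lmm, predict_mean
from .pattern_mixture import (PMMFit, PatternScheme, fit_pmm,
                              marginal_trajectory, marginalize_pmm,
                              pattern_trajectories)
from .selection_model import QuadConfig, SMFit, fit_sm
from .spm import DEFAULT_KNOTS, GHConfig, SPMFit, fit_spm

_LOG = logging.getLogger(__name__)
_Z95 = 1.959963984540054

MODEL_NAMES = ("lmm", "sm", "pmm", "spm")


def wald_p(estimate, se):
    """Two-sided p-value of z = estimate/SE under the standard normal."""
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(np.asarray(estimate, float) / np.asarray(se, float))
    return 2.0 * stats.norm.sf(z)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


@dataclasses.dataclass
class ComparisonTable:
    table: pd.DataFrame
    loglik: dict
    converged: dict
    errors: dict
    fits: dict
    meta: dict


def _rows_for(model, names, est, se):
    rows = []
    for name, e, s in zip(names, est, se):
        ok = np.isfinite(s)
        rows.append({
            "model": model, "parameter": name, "estimate": float(e),
            "se": float(s) if ok else np.nan,
            "ci_low": float(e - _Z95 * s) if ok else np.nan,
            "ci_high": float(e + _Z95 * s) if ok else np.nan,
            "p": float(wald_p(e, s)) if ok else np.nan,
        })
    return rows


def run_comparison(dataset: TrialDataset, models=MODEL_NAMES,
                   scheme: PatternScheme | None = None,
                   sm_quad: QuadConfig | None = None,
                   spm_quad: GHConfig | None = None,
                   knots=DEFAULT_KNOTS,
                   config: dict | None = None) -> ComparisonTable:
    """Fit each selected model with its module defaults; a model's failure
    is captured per-model and does not abort the rest."""
    rows, loglik, converged, errors, fits = [], {}, {}, {}, {}
    for model in models:
        t0 = time.perf_counter()
        try:
            if model == "lmm":
                fit = fit_lmm(dataset)
                rows += _rows_for("lmm", ["beta0", "beta1", "beta2"],
                                  fit.params.beta, fit.se)
            elif model == "sm":
                fit = fit_sm(dataset, quad=sm_quad)
                rows += _rows_for("sm", ["beta0", "beta1", "beta2"],
                                  fit.lmm.beta, fit.se_beta)
                rows += _rows_for("sm", ["psi0", "psi1", "psi2"],
                                  fit.dk.psi, fit.se_psi)
            elif model == "pmm":
                fit = fit_pmm(dataset, scheme=scheme)
                marg = marginalize_pmm(fit)
                rows += _rows_for("pmm", ["beta0", "beta1", "beta2"],
                                  marg.estimate, marg.se)
                for k in np.flatnonzero(fit.retained):
                    rows += _rows_for(
                        "pmm",
                        [f"beta0_p{k + 1}", f"beta1_p{k + 1}", f"beta2_p{k + 1}"],
                        fit.betas[k], fit.se_betas[k])
            elif model == "spm":
                fit = fit_spm(dataset, quad=spm_quad, knots=knots)
                rows += _rows_for("spm", ["beta0", "beta1", "beta2"],
                                  fit.params.lmm.beta, fit.se_beta)
                rows += _rows_for("spm", ["gamma"], [fit.params.gamma],
                                  [fit.se_gamma])
                rows += _rows_for("spm", ["alpha"], [fit.params.alpha],
                                  [fit.se_alpha])
                # baseline levels: SEs estimated on the log scale
                for q in range(fit.params.Q):
                    lx = np.log(fit.params.xi[q])
                    s = fit.se_log_xi[q]
                    ok = np.isfinite(s)
                    rows.append({
                        "model": "spm", "parameter": f"xi{q + 1}",
                        "estimate": float(fit.params.xi[q]),
                        "se": float(fit.params.xi[q] * s) if ok else np.nan,
                        "ci_low": float(np.exp(lx - _Z95 * s)) if ok else np.nan,
                        "ci_high": float(np.exp(lx + _Z95 * s)) if ok else np.nan,
                        "p": np.nan,
                    })
            else:
                raise ValueError(f"unknown model {model!r}")
            fits[model] = fit
            loglik[model] = float(fit.loglik)
            converged[model] = bool(fit.converged)
            errors[model] = None
            _LOG.info("%s fitted in %.2fs", model, time.perf_counter() - t0)
        except Exception as exc:  # captured, not raised
            errors[model] = f"{type(exc).__name__}: {exc}"
            converged[model] = False
            _LOG.warning("%s failed: %s", model, errors[model])
    if all(errors.get(m) for m in models):
        raise RuntimeError(f"all models failed: {errors}")
    meta = {"n_subjects": int(dataset.n_subjects),
            "config_hash": config_hash(config or {})}
    table = pd.DataFrame(rows)
    return ComparisonTable(table=table, loglik=loglik, converged=converged,
                           errors=errors, fits=fits, meta=meta)


def trajectory_curves(fits: dict, schedule, grid=None) -> dict:
    """Tabulated mean-score curves per model and arm on a time grid, plus
    per-pattern curves for the pattern-mixture fit and the baseline-hazard
    step curve for the joint fit."""
    t = np.asarray(grid if grid is not None else schedule.times_array(), float)
    out = {}
    frames = []
    for model, fit in fits.items():
        if fit is None:
            continue
        if isinstance(fit, LMMFit):
            params = fit.params
        elif isinstance(fit, SMFit):
            params = fit.lmm
        elif isinstance(fit, SPMFit):
            params = fit.params.lmm
        elif isinstance(fit, PMMFit):
            for arm in (0, 1):
                pat = pattern_trajectories(fit, arm, t)
                for k in range(fit.scheme.K):
                    if fit.retained[k]:
                        frames.append(pd.DataFrame({
                            "model": "pmm", "arm": arm, "curve": f"pattern{k + 1}",
                            "time": t, "mean_score": pat[k]}))
                frames.append(pd.DataFrame({
                    "model": "pmm", "arm": arm, "curve": "marginal",
                    "time": t, "mean_score": marginal_trajectory(fit, arm, t)}))
            continue
        else:
            continue
        for arm in (0, 1):
            frames.append(pd.DataFrame({
                "model": model, "arm": arm, "curve": "marginal",
                "time": t, "mean_score": predict_mean(params, arm, t)}))
    out["trajectories"] = (pd.concat(frames, ignore_index=True)
                           if frames else pd.DataFrame())
    spm_fit = next((f for f in fits.values() if isinstance(f, SPMFit)), None)
    if spm_fit is not None:
        out["baseline_hazard"] = baseline_hazard_table(spm_fit)
    return out


def baseline_hazard_table(fit: SPMFit) -> pd.DataFrame:
    """Fitted baseline hazard as (interval start, end, level, SE) rows."""
    edges = fit.params.interval_edges()
    rows = []
    for q in range(fit.params.Q):
        end = edges[q + 1] if q + 1 < edges.size else np.inf
        se = (fit.params.xi[q] * fit.se_log_xi[q]
              if np.isfinite(fit.se_log_xi[q]) else np.nan)
        rows.append((edges[q], end, fit.params.xi[q], se))
    return pd.DataFrame(rows, columns=["start", "end", "xi", "se"])


def plot_trajectories(curves: pd.DataFrame, path) -> None:
    """Optional figure of predicted trajectories (headless-safe)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for (model, arm, curve), sub in curves.groupby(["model", "arm", "curve"]):
        style = "-" if arm == 0 else "--"
        ax.plot(sub["time"], sub["mean_score"], style,
                label=f"{model} {curve} arm{arm}", alpha=0.7)
    ax.set_xlabel("months since inclusion")
    ax.set_ylabel("mean score (points)")
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
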