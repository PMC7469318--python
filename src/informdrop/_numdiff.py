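"""Central finite-difference derivatives for observed-information matrices."""

from __future__ import annotations

import numpy as np


def _steps(x, rel_step):
    x = np.asarray(x, dtype=float)
    return rel_step * np.maximum(1.0, np.abs(x))


def gradient(f, x, rel_step=1e-6):
    x = np.asarray(x, dtype=float)
    h = _steps(x, rel_step)
    g = np.zeros_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h[i]
        g[i] = (f(x + e) - f(x - e)) / (2.0 * h[i])
    return g


def hessian(f, x, rel_step=1e-4):
    """Symmetric central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    p = x.size
    h = _steps(x, rel_step)
    H = np.zeros((p, p))
    f0 = f(x)
    fp = np.zeros(p)
    fm = np.zeros(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = h[i]
        fp[i] = f(x + e)
        fm[i] = f(x - e)
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / h[i] ** 2
    for i in range(p):
        for j in range(i + 1, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x + ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2.0 * f0 - fm[i] - fm[j] + fmm
            ) / (2.0 * h[i] * h[j])
    return H


def safe_inverse(H):
    """Invert an observed-information matrix; (cov, ok) with ok=False when
    the matrix is singular or not positive definite."""
    H = 0.5 * (np.asarray(H) + np.asarray(H).T)
    try:
        eigvals = np.linalg.eigvalsh(H)
        if eigvals.min() <= 0 or not np.isfinite(H).all():
            return None, False
        return np.linalg.inv(H), True
    except np.linalg.LinAlgError:
        return None, False
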