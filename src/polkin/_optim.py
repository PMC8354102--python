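"""Shared numerics for the likelihood fits: multi-start optimization and
confidence intervals from the numerically computed Hessian."""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

Z95 = 1.959963984540054


def numeric_hessian(f: Callable[[np.ndarray], float], x: np.ndarray) -> np.ndarray:
    """Central-difference Hessian; step 1e-4 * max(1, |x_i|)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    h = 1e-4 * np.maximum(1.0, np.abs(x))
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[[i, j]] += [h[i], h[j]]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def hessian_ses(nll: Callable[[np.ndarray], float], x: np.ndarray) -> np.ndarray | None:
    """Standard errors from the inverse Hessian of a negative log likelihood.

    Returns None when the Hessian is not positive definite (quadratic
    approximation invalid).
    """
    H = numeric_hessian(nll, x)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    var = np.diag(cov)
    if np.any(var <= 0) or not np.all(np.isfinite(var)):
        return None
    return np.sqrt(var)


def multistart_minimize(
    nll: Callable[[np.ndarray], float],
    starts: Sequence[np.ndarray],
    bounds: Sequence[tuple[float, float]],
    tie_key: Callable[[np.ndarray], float] | None = None,
) -> "object":
    """L-BFGS-B from several starts; best (then tie-broken) result wins."""
    best = None
    best_key = None
    for x0 in starts:
        try:
            res = minimize(nll, np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=bounds)
        except (ValueError, FloatingPointError):
            continue
        if not np.isfinite(res.fun):
            continue
        key = (round(float(res.fun), 6), tie_key(res.x) if tie_key else 0.0)
        if best is None or key < best_key:
            best, best_key = res, key
    return best
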