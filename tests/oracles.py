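"""Independent reference implementations used only to check the package.

These deliberately avoid the code paths they validate: lifetimes via
log-linear regression on noise-free expectations, biexponential optima via
exhaustive grid search over the lifetime pair with the component
amplitudes solved per grid point by multiplicative EM updates (the
classical Richardson-Lucy iteration for a linear Poisson mixture).
"""

from __future__ import annotations

import math

import numpy as np


def loglinear_lifetime(t: np.ndarray, y: np.ndarray) -> float:
    """Lifetime from an unweighted straight-line fit of log(y) vs t."""
    sel = y > 0
    slope, _ = np.polyfit(t[sel], np.log(y[sel]), 1)
    return -1.0 / slope


def poisson_deviance(y: np.ndarray, m: np.ndarray) -> float:
    """Total Poisson deviance of counts y under model m."""
    m = np.maximum(m, 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / m), 0.0)
    return float(np.sum(2.0 * (m - y + term)))


def em_amplitudes(X: np.ndarray, y: np.ndarray, n_iter: int = 500) -> np.ndarray:
    """Maximum-likelihood non-negative amplitudes for y ~ Poisson(X @ a)."""
    col = X.sum(axis=0)
    a = np.full(X.shape[1], max(y.sum(), 1.0) / max(col.sum(), 1e-12))
    for _ in range(n_iter):
        m = np.maximum(X @ a, 1e-12)
        a = a * (X.T @ (y / m)) / np.maximum(col, 1e-12)
    return a


def grid_search_biexp(
    t: np.ndarray,
    y: np.ndarray,
    tau_fast_grid: np.ndarray,
    tau_slow_grid: np.ndarray,
):
    """Exhaustive (tau_fast, tau_slow) grid search in the Poisson metric.

    Returns (best_deviance, tau_fast, tau_slow, amplitudes).
    """
    best = (math.inf, None, None, None)
    for tf in tau_fast_grid:
        ef = np.exp(-t / tf)
        for ts in tau_slow_grid:
            if ts < tf:
                continue
            X = np.stack([ef, np.exp(-t / ts)], axis=1)
            amps = em_amplitudes(X, y)
            obj = poisson_deviance(y, X @ amps)
            if obj < best[0]:
                best = (obj, float(tf), float(ts), amps)
    return best


def tail_window(counts: np.ndarray, channel_width: float, offset_ns: float = 0.200):
    """Tail channels starting ceil(offset/width) after the peak, with times."""
    start = int(np.argmax(counts)) + int(math.ceil(offset_ns / channel_width))
    y = np.asarray(counts[start:], dtype=float)
    t = np.arange(y.size) * channel_width
    return t, y, start


def profiled_deviance(t, y, tau_fast, tau_slow, a_fast):
    """Deviance at the given decay shape with the total scale profiled out.

    For a pure scaling m = c·s the Poisson MLE of c is Σy/Σs in closed
    form, so this reproduces the objective an optimiser with a free total
    amplitude would report for these shape parameters.
    """
    s = a_fast * np.exp(-t / tau_fast) + (1 - a_fast) * np.exp(-t / tau_slow)
    c = float(y.sum() / s.sum())
    return poisson_deviance(y, c * s)
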