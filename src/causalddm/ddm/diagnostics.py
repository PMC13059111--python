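"""Convergence diagnostics and posterior summaries.

Classic Gelman–Rubin R̂ (between/within-chain variance ratio, floored at 1),
shortest highest-density intervals by sorted-sample sweep, and HDI-based
credible differences between paired posterior sample sets.
"""

from __future__ import annotations

import numpy as np

__all__ = ["gelman_rubin", "hdi", "credible_difference"]


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor R̂ for one scalar parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length chains.  Uses the
    classic estimator sqrt(V̂ / W) with V̂ = (n−1)/n·W + B/n; the ratio is
    floored at 1 so identical chains report exactly 1.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 equal-length chains")
    m, n = x.shape
    chain_means = x.mean(1)
    w = float(np.mean(x.var(1, ddof=1)))
    b = n * float(np.var(chain_means, ddof=1))
    if w <= 0.0:
        return 1.0 if b <= 0.0 else np.inf
    v_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(max(1.0, v_hat / w)))


def hdi(samples, mass: float = 0.95):
    """Shortest interval containing ``mass`` posterior probability.

    Sorted-samples sweep over all windows of the required length.
    """
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise ValueError("need >= 100 draws for a stable HDI")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def credible_difference(samples_a, samples_b, mass: float = 0.95):
    """Draw-wise difference of two paired posterior sample sets.

    Returns ``(hdi_low, hdi_high, credible)`` where credible means the
    difference HDI excludes zero.  Samples must be paired by iteration.
    """
    a = np.asarray(samples_a, dtype=float).ravel()
    b = np.asarray(samples_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("sample sets must have equal draw counts")
    lo, hi = hdi(a - b, mass)
    return lo, hi, bool(lo > 0.0 or hi < 0.0)
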