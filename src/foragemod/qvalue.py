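"""Storey q-values with pi0 estimation.

The q-value of a test is the minimum positive false discovery rate at
which it would be called significant. pi0 (the estimated proportion of
true nulls) is estimated from the density of large p-values; with pi0
forced to 1 the procedure reduces to the Benjamini-Hochberg step-up.
"""

from __future__ import annotations

import numpy as np

__all__ = ["estimate_pi0", "qvalues"]


def estimate_pi0(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Estimate the true-null proportion by smoothing over tail thresholds.

    For each lambda, pi0(lambda) = #{p > lambda} / (m (1 - lambda)); a
    cubic fit over the lambda grid is evaluated at the largest lambda.
    Small p-value sets (< 100) fall back to the single lambda = 0.5
    estimate: the smoother's tail extrapolation is too variable on a
    sparse p-grid and deflates pi0.
    """
    p = np.asarray(pvalues, float)
    m = p.size
    if m == 0:
        return 1.0
    if lambdas is None:
        lambdas = np.arange(0.05, 0.95, 0.05)
    lambdas = np.asarray(lambdas, float)
    if m < 100 or lambdas.size < 4:
        lam = 0.5
        pi0 = (p > lam).sum() / (m * (1 - lam))
        return float(min(max(pi0, 1.0 / m), 1.0))
    pi0s = np.array([(p > lam).sum() / (m * (1 - lam)) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0s, 3)
    pi0 = float(np.polyval(coef, lambdas.max()))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(pvalues: np.ndarray, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """q-values in the input order, plus the pi0 used.

    q is monotone non-decreasing in p by construction.
    """
    p = np.asarray(pvalues, float)
    m = p.size
    if m == 0:
        return np.array([]), 1.0
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p)
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out, float(pi0)
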