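"""Shared statistical helpers: BH adjustment and variance moderation.

Benjamini-Hochberg delegates to statsmodels.  The empirical-Bayes variance
shrinkage used by the moderated paired t-test is estimated by moment matching
on the log sample variances: for chi-square distributed s^2 with d degrees of
freedom, log s^2 has known mean/variance offsets expressible through the
digamma/trigamma functions, which yields closed-form method-of-moments
estimates of the prior degrees of freedom d0 and prior variance s0^2.
"""

from __future__ import annotations

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "estimate_variance_prior", "trigamma_inverse"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def trigamma_inverse(y: float, tol: float = 1e-10, max_iter: int = 60) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below (on the scale 1/x, where
    trigamma is nearly linear) converges from the asymptotic start x ~ 1/y.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from per-feature variances.

    Matches the mean and variance of log s^2 across features against the
    scaled-F model s^2 ~ s0^2 * F(df, d0).  Returns d0 = inf when the
    observed spread of log variances is no larger than the chi-square
    sampling spread alone (i.e. no evidence of variance heterogeneity).
    Raises when all variances are zero.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size == 0:
        raise ValueError("all per-feature variances are zero")
    z = np.log(positive)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    n = e.size
    if n < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if not np.isfinite(e_var):
        raise FloatingPointError("non-finite moment estimate for d0")
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0sq = np.exp(
        e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)
    ) if np.isfinite(d0) else np.exp(e_mean)
    return float(d0), float(s0sq)
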