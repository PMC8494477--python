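"""Frequentist counterparts on the binomial prevalence model.

Maximum-likelihood estimation, percentile-bootstrap confidence intervals,
the global-null p-value (no unit in the population has an effect), compound
nulls of the form gamma < gamma0 (e.g. the "majority null" gamma < 0.5) and
the frequentist prevalence lower bound derived from that family of nulls.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .core import TestResultCounts, theta_from_gamma

__all__ = [
    "mle",
    "global_null_pvalue",
    "compound_null_pvalue",
    "freq_lower_bound",
    "bootstrap_ci",
]


def mle(counts: TestResultCounts) -> float:
    """Maximum-likelihood estimate of prevalence.

    ``(k/n - alpha) / (1 - alpha)`` clamped to [0, 1]; identical to the
    Bayesian MAP under the uniform prior.
    """
    g = (counts.k / counts.n - counts.alpha) / (1.0 - counts.alpha)
    return float(min(max(g, 0.0), 1.0))


def global_null_pvalue(counts: TestResultCounts) -> float:
    """P(X > k) for X ~ Binomial(n, alpha): evidence against the global null.

    Under the global null every positive test is a false positive, so the
    count of positives is binomial with success probability alpha.  The
    strict upper tail is used: the p-value is the probability of seeing
    *more* positives than observed.
    """
    return float(stats.binom.sf(counts.k, counts.n, counts.alpha))


def compound_null_pvalue(
    counts: TestResultCounts, gamma0: float, strict: bool = False
) -> float:
    """p-value against the compound null gamma < gamma0.

    The null probability of a positive test is largest at gamma = gamma0,
    where theta = (1 - gamma0) * alpha + gamma0, so the supremum p-value
    over the compound null is the binomial tail at that theta.  By default
    the tail is P(X >= k); ``strict=True`` gives P(X > k) for callers who
    prefer the convention used by :func:`global_null_pvalue`.
    """
    if not 0.0 <= gamma0 < 1.0:
        raise ValueError(f"gamma0 must lie in [0, 1), got {gamma0}")
    theta = theta_from_gamma(gamma0, counts.alpha)
    k = counts.k if strict else counts.k - 1
    return float(stats.binom.sf(k, counts.n, theta))


def freq_lower_bound(
    counts: TestResultCounts,
    level: float = 0.05,
    strict: bool = False,
    tol: float = 1e-6,
) -> float:
    """Frequentist lower bound on prevalence at significance ``level``.

    The largest gamma_c such that the compound null gamma < gamma_c is
    rejected, i.e. ``compound_null_pvalue(counts, gamma_c) < level``.  The
    p-value is monotone increasing in gamma_c, so the bound is found by
    bisection; returns 0 when even the global-null family is not rejected.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")

    def p(g: float) -> float:
        return compound_null_pvalue(counts, g, strict=strict)

    if p(0.0) >= level:
        return 0.0
    hi_probe = 1.0 - tol
    if p(hi_probe) < level:
        return 1.0
    lo, hi = 0.0, hi_probe  # p(lo) < level <= p(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if p(mid) < level:
            lo = mid
        else:
            hi = mid
    return float(lo)


def bootstrap_ci(
    counts: TestResultCounts,
    reps: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the prevalence MLE.

    The per-unit binary outcome is the sampling unit, so resampling the
    outcome vector with replacement is equivalent to drawing
    k* ~ Binomial(n, k/n) and re-estimating.
    """
    if reps < 100:
        raise ValueError(f"need at least 100 bootstrap replicates, got {reps}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    rng = np.random.default_rng(seed)
    k_star = rng.binomial(counts.n, counts.k / counts.n, size=reps)
    g_star = np.clip(
        (k_star / counts.n - counts.alpha) / (1.0 - counts.alpha), 0.0, 1.0
    )
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(g_star, [tail, 1.0 - tail])
    return (float(lo), float(hi))
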