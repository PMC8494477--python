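"""Exact Bayesian posterior for the population prevalence of true positives.

The model: each of ``n`` sampled units (participants, neurons, ...) is given
a within-unit statistical test with false positive rate ``alpha``.  If a
proportion ``gamma`` of the population would show a true positive result
under this test procedure, the probability that a randomly sampled unit
tests positive is

    theta = (1 - gamma) * alpha + gamma

With a Beta(r, s) prior on theta and a binomial likelihood for the observed
count ``k`` of positive units, the posterior on theta is Beta(k + r,
n - k + s) truncated to [alpha, 1].  Prevalence is the deterministic
reparameterisation gamma = (theta - alpha) / (1 - alpha), with support
[0, 1].  This module exposes the posterior density, CDF, quantiles, the MAP
point estimate, highest posterior density intervals and lower-bound
quantiles, all on the prevalence (gamma) scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BetaPrior",
    "TestResultCounts",
    "PrevalencePosterior",
    "PosteriorSummary",
    "theta_from_gamma",
    "gamma_from_theta",
    "posterior_density",
    "posterior_cdf",
    "map_estimate",
    "hpdi",
    "lower_bound",
    "summarize",
]

# Below this truncation mass the truncated and untruncated posteriors are
# numerically identical, so renormalisation is skipped.
_TRUNC_EPS = 1e-300


@dataclass(frozen=True)
class BetaPrior:
    """Beta(r, s) prior on the positive-test probability theta.

    The default r = s = 1 is the uniform prior, which is also uniform on
    the prevalence scale.
    """

    r: float = 1.0
    s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r > 0 and self.s > 0):
            raise ValueError(f"prior shapes must be positive, got r={self.r}, s={self.s}")


UNIFORM_PRIOR = BetaPrior(1.0, 1.0)


@dataclass(frozen=True)
class TestResultCounts:
    """Sufficient statistic for single-group prevalence inference.

    Parameters
    ----------
    k : int
        Number of units with a positive (significant) within-unit test.
    n : int
        Number of units tested.
    alpha : float
        False positive rate of the within-unit test, common to all units.
    """

    k: int
    n: int
    alpha: float

    __test__ = False  # keep pytest from collecting this Test*-named class

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"need at least one tested unit, got n={self.n}")
        if not (0 <= self.k <= self.n):
            raise ValueError(f"k must satisfy 0 <= k <= n, got k={self.k}, n={self.n}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie strictly in (0, 1), got {self.alpha}")


def theta_from_gamma(gamma: float, alpha: float, beta: float = 1.0) -> float:
    """Positive-test probability implied by prevalence ``gamma``.

    ``theta = (1 - gamma) * alpha + gamma * beta`` where ``alpha`` is the
    false positive rate and ``beta`` the test sensitivity.  The inferential
    model in this package fixes ``beta = 1`` (prevalence of true positives);
    the general form is provided for forward simulation.
    """
    g, a, b = float(gamma), float(alpha), float(beta)
    for name, v in (("gamma", g), ("alpha", a), ("beta", b)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    if a >= 1.0:
        raise ValueError("alpha must be < 1")
    return (1.0 - g) * a + g * b


def gamma_from_theta(theta: float, alpha: float) -> float:
    """Prevalence implied by positive-test probability ``theta`` (beta = 1)."""
    t, a = float(theta), float(alpha)
    if t > 1.0:
        raise ValueError(f"theta must be <= 1, got {t}")
    if t < a:
        raise ValueError(f"theta={t} below the posterior support lower edge alpha={a}")
    return (t - a) / (1.0 - a)


@dataclass(frozen=True)
class PrevalencePosterior:
    """Truncated-beta posterior on theta, reparameterised to prevalence.

    Internally a Beta(k + r, n - k + s) distribution on theta truncated to
    [alpha, 1]; all public methods work on the gamma = (theta - alpha) /
    (1 - alpha) scale with support [0, 1].
    """

    counts: TestResultCounts
    prior: BetaPrior = field(default_factory=BetaPrior)

    @property
    def a(self) -> float:
        return self.counts.k + self.prior.r

    @property
    def b(self) -> float:
        return self.counts.n - self.counts.k + self.prior.s

    @property
    def _dist(self) -> stats.rv_continuous:
        return stats.beta(self.a, self.b)

    @property
    def _trunc_mass(self) -> float:
        """Posterior mass of the untruncated beta on [alpha, 1]."""
        m = float(self._dist.sf(self.counts.alpha))
        if m < _TRUNC_EPS:
            raise FloatingPointError(
                "truncation region [alpha, 1] carries numerically zero beta mass"
            )
        return m

    def _theta(self, gamma):
        return self.counts.alpha + (1.0 - self.counts.alpha) * np.asarray(gamma, float)

    def density(self, gamma):
        """Posterior density of prevalence; zero outside [0, 1]."""
        g = np.asarray(gamma, dtype=float)
        cdf_lo = float(self._dist.cdf(self.counts.alpha))
        if cdf_lo < _TRUNC_EPS:
            norm = 1.0  # truncation irrelevant: skip renormalisation
        else:
            norm = self._trunc_mass
        out = np.where(
            (g >= 0.0) & (g <= 1.0),
            self._dist.pdf(self._theta(np.clip(g, 0.0, 1.0)))
            * (1.0 - self.counts.alpha)
            / norm,
            0.0,
        )
        return out if out.ndim else float(out)

    def cdf(self, gamma):
        """P(prevalence <= gamma)."""
        g = np.clip(np.asarray(gamma, dtype=float), 0.0, 1.0)
        # survival-function form stays accurate when the truncation mass is tiny
        out = 1.0 - self._dist.sf(self._theta(g)) / self._trunc_mass
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def quantile(self, q):
        """Inverse CDF on the prevalence scale."""
        q = np.asarray(q, dtype=float)
        if np.any((q < 0.0) | (q > 1.0)):
            raise ValueError("quantile levels must lie in [0, 1]")
        theta_q = self._dist.isf(self._trunc_mass * (1.0 - q))
        out = (np.clip(theta_q, self.counts.alpha, 1.0) - self.counts.alpha) / (
            1.0 - self.counts.alpha
        )
        out = np.clip(out, 0.0, 1.0)
        return out if out.ndim else float(out)

    def map_estimate(self) -> float:
        return map_estimate(self.counts, self.prior)

    def hpdi(self, mass: float = 0.96) -> tuple[float, float]:
        return hpdi(self, mass)

    def lower_bound(self, level: float = 0.95) -> float:
        return lower_bound(self, level)


def posterior_density(gamma, posterior: PrevalencePosterior):
    """Functional alias for :meth:`PrevalencePosterior.density`."""
    return posterior.density(gamma)


def posterior_cdf(gamma, posterior: PrevalencePosterior):
    """Functional alias for :meth:`PrevalencePosterior.cdf`."""
    return posterior.cdf(gamma)


def map_estimate(counts: TestResultCounts, prior: BetaPrior | None = None) -> float:
    """Posterior mode of prevalence.

    Under the uniform prior this is available in closed form,
    ``(k/n - alpha) / (1 - alpha)`` clamped to [0, 1].  For a general beta
    prior the mode of the truncated Beta(k + r, n - k + s) on theta is
    located from the shape parameters (interior stationary point or a
    support boundary) and mapped to the prevalence scale.
    """
    prior = prior or UNIFORM_PRIOR
    k, n, alpha = counts.k, counts.n, counts.alpha
    a, b = k + prior.r, n - k + prior.s
    if a > 1.0 and b > 1.0:
        theta_mode = (a - 1.0) / (a + b - 2.0)
        theta_mode = min(max(theta_mode, alpha), 1.0)
    elif a <= 1.0 and b > 1.0:
        theta_mode = alpha  # density decreasing on the support
    elif a > 1.0 and b <= 1.0:
        theta_mode = 1.0  # density increasing on the support
    else:
        # U-shaped beta: the truncated mode sits at whichever edge is denser
        dist = stats.beta(a, b)
        theta_mode = alpha if dist.pdf(alpha) >= dist.pdf(1.0 - 1e-12) else 1.0
    return gamma_from_theta(theta_mode, alpha)


def hpdi(posterior: PrevalencePosterior, mass: float = 0.96) -> tuple[float, float]:
    """Highest posterior density interval of prevalence.

    The shortest interval containing ``mass`` posterior probability.  The
    posterior is unimodal, so the interval is found by minimising the width
    ``quantile(u + mass) - quantile(u)`` over the lower tail probability
    ``u``.  When the mode sits on a support boundary (k/n <= alpha, or
    k = n) the interval is one-sided, anchored at that boundary.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError(f"interval mass must lie in (0, 1), got {mass}")
    mode = posterior.map_estimate()
    if mode <= 0.0:
        return (0.0, float(posterior.quantile(mass)))
    if mode >= 1.0:
        return (float(posterior.quantile(1.0 - mass)), 1.0)

    def width(u: float) -> float:
        return float(posterior.quantile(u + mass) - posterior.quantile(u))

    res = optimize.minimize_scalar(
        width, bounds=(0.0, 1.0 - mass), method="bounded", options={"xatol": 1e-9}
    )
    u = float(res.x)
    # the optimum can sit exactly on a tail boundary; check both edges too
    cands = [(width(c), c) for c in (u, 0.0, 1.0 - mass)]
    _, u = min(cands)
    return (float(posterior.quantile(u)), float(posterior.quantile(u + mass)))


def lower_bound(posterior: PrevalencePosterior, level: float = 0.95) -> float:
    """Prevalence q such that P(gamma > q) = level (Bayesian lower bound)."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"credibility level must lie in (0, 1), got {level}")
    return float(posterior.quantile(1.0 - level))


@dataclass(frozen=True)
class PosteriorSummary:
    """Point and interval summary of a prevalence posterior."""

    map: float
    hpdi_lo: float
    hpdi_hi: float
    hpdi_mass: float = 0.96
    lower_bounds: dict[float, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.hpdi_lo <= self.map <= self.hpdi_hi <= 1.0):
            raise ValueError(
                "summary must satisfy 0 <= hpdi_lo <= map <= hpdi_hi <= 1, got "
                f"[{self.hpdi_lo}, {self.map}, {self.hpdi_hi}]"
            )


def summarize(
    counts: TestResultCounts,
    prior: BetaPrior | None = None,
    mass: float = 0.96,
    lower_bound_levels: tuple[float, ...] = (0.95,),
) -> PosteriorSummary:
    """One-call MAP + HPDI + lower-bound summary for a single group."""
    post = PrevalencePosterior(counts, prior or UNIFORM_PRIOR)
    lo, hi = post.hpdi(mass)
    m = post.map_estimate()
    # guard against optimizer round-off placing the mode a hair outside
    lo, hi = min(lo, m), max(hi, m)
    return PosteriorSummary(
        map=m,
        hpdi_lo=lo,
        hpdi_hi=hi,
        hpdi_mass=mass,
        lower_bounds={lv: post.lower_bound(lv) for lv in lower_bound_levels},
    )
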