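"""Synthetic-data generators and analytic characterisations.

Three generators emulate typical experimental designs feeding prevalence
inference:

* a hierarchical Gaussian model of trial data — participant means drawn
  from a normal population distribution (or a mixture of normals for
  heterogeneous populations), trials normal around each mean;
* an ERP-style time-series model — white-noise trials with an additive
  Gaussian-bump activation whose amplitude and peak latency vary across
  participants;
* a correlated two-test binary-outcome model — joint positive/negative
  results of two tests with given prevalences and a population correlation
  between the two latent effect indicators.

Analytic companions: within-participant and second-level t-tests, the
power of the population-mean t-test via the noncentral t distribution, and
exact expectations (over the binomial sampling distribution of k) of the
prevalence MAP, lower bound and HPDI width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .core import (
    PrevalencePosterior,
    TestResultCounts,
    map_estimate,
    theta_from_gamma,
)
from .differences import WithinGroupCounts

__all__ = [
    "MixtureComponent",
    "HierarchicalModelParams",
    "ERPSimParams",
    "ERPSimResult",
    "TwoTestGroundTruth",
    "simulate_hierarchical",
    "within_participant_ttest",
    "summary_stat_group_ttest",
    "simulate_erp",
    "joint_true_positive_rate",
    "two_test_cell_probabilities",
    "simulate_two_tests",
    "population_ttest_power",
    "expected_prevalence_summaries",
]


class MixtureComponent(NamedTuple):
    """One component of the population distribution of participant means."""

    weight: float
    mu_pop: float
    sigma_b: float


@dataclass(frozen=True)
class HierarchicalModelParams:
    """Hierarchical Gaussian trial model.

    Participant means mu_i are drawn from the mixture of normal components
    (a single component is the standard model mu_i ~ N(mu_pop, sigma_b^2));
    trial j of participant i is y_ij ~ N(mu_i, sigma_w^2).  The marginal
    distribution of within-participant means under a single component is
    N(mu_pop, sigma_b^2 + sigma_w^2 / T).
    """

    n_participants: int
    n_trials: int
    components: Sequence[MixtureComponent]
    sigma_w: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1 or self.n_trials < 1:
            raise ValueError("need at least one participant and one trial")
        comps = tuple(MixtureComponent(*c) for c in self.components)
        if not comps:
            raise ValueError("need at least one mixture component")
        w = np.array([c.weight for c in comps])
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError(f"component weights must be non-negative and sum to 1, got {w}")
        if any(c.sigma_b < 0 for c in comps):
            raise ValueError("sigma_b must be non-negative")
        if self.sigma_w < 0:
            raise ValueError("sigma_w must be non-negative")
        object.__setattr__(self, "components", comps)

    @classmethod
    def single(
        cls,
        n_participants: int,
        n_trials: int,
        mu_pop: float,
        sigma_b: float,
        sigma_w: float,
        seed: int = 0,
    ) -> "HierarchicalModelParams":
        """Convenience constructor for the single-component base model."""
        return cls(
            n_participants,
            n_trials,
            [MixtureComponent(1.0, mu_pop, sigma_b)],
            sigma_w,
            seed,
        )


def simulate_hierarchical(params: HierarchicalModelParams) -> np.ndarray:
    """Draw an (N, T) matrix of trial measurements from the hierarchical model."""
    rng = np.random.default_rng(params.seed)
    n, t = params.n_participants, params.n_trials
    weights = np.array([c.weight for c in params.components])
    which = rng.choice(len(weights), size=n, p=weights)
    mus = np.array([c.mu_pop for c in params.components])[which]
    sbs = np.array([c.sigma_b for c in params.components])[which]
    participant_means = rng.normal(mus, sbs)
    return rng.normal(participant_means[:, None], params.sigma_w, size=(n, t))


def within_participant_ttest(
    trials: np.ndarray, mu0: float = 0.0, sided: Literal["two", "one"] = "two"
) -> tuple[np.ndarray, np.ndarray]:
    """One-sample t-test per participant (row) against ``mu0``.

    Returns per-participant arrays of t statistics and p-values.  The
    one-sided alternative is mean > mu0.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 2 or trials.shape[1] < 2:
        raise ValueError("trials must be an (N, T) matrix with T >= 2")
    if np.any(trials.std(axis=1) == 0.0):
        bad = int(np.flatnonzero(trials.std(axis=1) == 0.0)[0])
        raise ValueError(f"participant {bad} has zero trial variance; t-test undefined")
    alternative = "two-sided" if sided == "two" else "greater"
    res = stats.ttest_1samp(trials, mu0, axis=1, alternative=alternative)
    return np.asarray(res.statistic), np.asarray(res.pvalue)


def summary_stat_group_ttest(
    participant_means: np.ndarray, mu0: float = 0.0
) -> tuple[float, float]:
    """Second-level one-sample t-test on per-participant mean values."""
    means = np.asarray(participant_means, dtype=float)
    if means.ndim != 1 or len(means) < 2:
        raise ValueError("need a 1-d array of at least two participant means")
    if means.std() == 0.0:
        raise ValueError("zero variance across participants; t-test undefined")
    res = stats.ttest_1samp(means, mu0)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class ERPSimParams:
    """ERP-style simulation: white noise plus a participant-specific bump.

    Each trial is unit-variance white noise over ``n_timepoints`` samples
    (1 ms spacing).  Each participant with an effect receives one amplitude
    drawn uniformly from ``amplitude_range`` and one peak latency drawn
    uniformly from ``peak_window`` (ms); the Gaussian template
    amplitude * exp(-(t - peak)^2 / (2 * template_sd^2)) is added to every
    trial of that participant.  ``n_with_effect`` limits the effect to the
    first so-many participants (the rest get amplitude 0), emulating
    subgroup designs.
    """

    n_participants: int
    n_trials: int
    n_timepoints: int = 600
    template_sd: float = 20.0
    amplitude_range: tuple[float, float] = (0.0, 0.6)
    peak_window: tuple[float, float] = (100.0, 400.0)
    n_with_effect: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_range[0] > self.amplitude_range[1]:
            raise ValueError("amplitude_range must satisfy lo <= hi")
        if not (0.0 <= self.peak_window[0] <= self.peak_window[1] <= self.n_timepoints - 1):
            raise ValueError("peak_window must lie within the time axis")
        k = self.n_with_effect
        if k is not None and not 0 <= k <= self.n_participants:
            raise ValueError("n_with_effect must lie in [0, n_participants]")


class ERPSimResult(NamedTuple):
    data: np.ndarray  # (participants, trials, timepoints)
    amplitudes: np.ndarray  # per-participant ground-truth amplitude
    peak_times: np.ndarray  # per-participant ground-truth peak latency (ms)


def simulate_erp(params: ERPSimParams) -> ERPSimResult:
    """Simulate ERP-like trials and return data plus per-participant truth."""
    rng = np.random.default_rng(params.seed)
    n, t, s = params.n_participants, params.n_trials, params.n_timepoints
    n_eff = params.n_with_effect if params.n_with_effect is not None else n
    amplitudes = rng.uniform(*params.amplitude_range, size=n)
    amplitudes[n_eff:] = 0.0
    peaks = rng.uniform(*params.peak_window, size=n)
    time = np.arange(s, dtype=float)
    sd = max(params.template_sd, 1e-12)  # template_sd -> 0: bump confined to one sample
    bump = amplitudes[:, None] * np.exp(-0.5 * ((time[None, :] - peaks[:, None]) / sd) ** 2)
    data = rng.standard_normal((n, t, s)) + bump[:, None, :]
    return ERPSimResult(data, amplitudes, peaks)


@dataclass(frozen=True)
class TwoTestGroundTruth:
    """Ground truth for two correlated tests applied to one population.

    ``rho12`` is the Pearson correlation between the two binary
    true-positive indicators across the population; feasible values are
    restricted by the margins gamma1, gamma2.
    """

    gamma1: float
    gamma2: float
    rho12: float
    alpha: float

    def __post_init__(self) -> None:
        for name, v in (("gamma1", self.gamma1), ("gamma2", self.gamma2)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie strictly in (0, 1), got {self.alpha}")
        if not -1.0 <= self.rho12 <= 1.0:
            raise ValueError(f"rho12 must lie in [-1, 1], got {self.rho12}")


def joint_true_positive_rate(gt: TwoTestGroundTruth) -> float:
    """Proportion gamma11 with a true positive on both tests.

    For a pair of Bernoulli margins with correlation rho12,
    gamma11 = gamma1 * gamma2
            + rho12 * sqrt(gamma1 (1 - gamma1) gamma2 (1 - gamma2)).
    Raises if the implied joint cell probabilities are infeasible.
    """
    g1, g2, rho = gt.gamma1, gt.gamma2, gt.rho12
    g11 = g1 * g2 + rho * np.sqrt(g1 * (1.0 - g1) * g2 * (1.0 - g2))
    cells = (g11, g1 - g11, g2 - g11, 1.0 - g1 - g2 + g11)
    if any(c < -1e-12 or c > 1.0 + 1e-12 for c in cells):
        raise ValueError(
            f"correlation rho12={rho} infeasible for margins ({g1}, {g2}): "
            f"implied joint probabilities {np.round(cells, 6)}"
        )
    return float(np.clip(g11, 0.0, 1.0))


def two_test_cell_probabilities(gt: TwoTestGroundTruth) -> np.ndarray:
    """Observed-outcome cell probabilities (theta11, theta10, theta01, theta00).

    With false positive rate alpha and sensitivity 1, a unit with no true
    effect on a test still goes positive with probability alpha, so

        theta11 = gamma11 + alpha^2 gamma00 + alpha gamma01 + alpha gamma10
        theta10 = alpha + (1 - alpha) gamma1 - theta11
        theta01 = alpha + (1 - alpha) gamma2 - theta11
        theta00 = 1 - theta11 - theta10 - theta01
    """
    a = gt.alpha
    g11 = joint_true_positive_rate(gt)
    g10 = gt.gamma1 - g11
    g01 = gt.gamma2 - g11
    g00 = 1.0 - g11 - g10 - g01
    th11 = g11 + a * a * g00 + a * g01 + a * g10
    th10 = a + (1.0 - a) * gt.gamma1 - th11
    th01 = a + (1.0 - a) * gt.gamma2 - th11
    th00 = 1.0 - th11 - th10 - th01
    theta = np.array([th11, th10, th01, th00])
    if np.any(theta < -1e-12) or np.any(theta > 1.0 + 1e-12):
        raise ValueError(f"infeasible ground truth: cell probabilities {theta}")
    return np.clip(theta, 0.0, 1.0)


def simulate_two_tests(
    gt: TwoTestGroundTruth, n: int, seed: int = 0
) -> WithinGroupCounts:
    """One multinomial draw of joint test-outcome counts for n units."""
    if n < 1:
        raise ValueError(f"need n >= 1, got {n}")
    theta = two_test_cell_probabilities(gt)
    rng = np.random.default_rng(seed)
    k11, k10, k01, _ = rng.multinomial(n, theta / theta.sum())
    return WithinGroupCounts(int(k11), int(k10), int(k01), n, gt.alpha)


def population_ttest_power(
    n_participants: int,
    n_trials: int,
    mu_pop: float,
    sigma_b: float,
    sigma_w: float,
    alpha_level: float = 0.05,
) -> float:
    """Power of the two-sided second-level one-sample t-test.

    Under the hierarchical model the per-participant means are
    N(mu_pop, sigma_b^2 + sigma_w^2 / T), giving standardised effect size
    d = mu_pop / sqrt(sigma_b^2 + sigma_w^2 / T), noncentrality
    d * sqrt(N) and df = N - 1.
    """
    if n_participants < 2:
        raise ValueError("need at least two participants")
    if not 0.0 < alpha_level < 1.0:
        raise ValueError(f"alpha_level must lie in (0, 1), got {alpha_level}")
    d = mu_pop / np.sqrt(sigma_b**2 + sigma_w**2 / n_trials)
    df = n_participants - 1
    ncp = d * np.sqrt(n_participants)
    tcrit = stats.t.isf(alpha_level / 2.0, df)
    power = stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    if np.isnan(power):
        # the noncentral-t tail routine overflows at large noncentrality;
        # fall back on the standard normal approximation of the nct tail
        def approx_sf(t: float) -> float:
            return float(
                stats.norm.sf((t * (1.0 - 1.0 / (4.0 * df)) - ncp)
                              / np.sqrt(1.0 + t * t / (2.0 * df)))
            )

        power = approx_sf(tcrit) + (1.0 - approx_sf(-tcrit))
    return float(min(max(power, 0.0), 1.0))


def expected_prevalence_summaries(
    gamma: float,
    alpha: float,
    n: int,
    mass: float = 0.96,
    lower_level: float = 0.95,
) -> tuple[float, float, float]:
    """Exact expectations of the MAP, lower bound and HPDI width.

    Averages each posterior summary over the sampling distribution
    k ~ Binomial(n, theta(gamma)) by full enumeration of k = 0..n.
    Returns (E[MAP], E[lower bound], E[HPDI width]).
    """
    theta = theta_from_gamma(gamma, alpha)
    pmf = stats.binom.pmf(np.arange(n + 1), n, theta)
    e_map = e_lb = e_width = 0.0
    for k, w in enumerate(pmf):
        if w == 0.0:
            continue
        counts = TestResultCounts(k, n, alpha)
        post = PrevalencePosterior(counts)
        lo, hi = post.hpdi(mass)
        e_map += w * map_estimate(counts)
        e_lb += w * post.lower_bound(lower_level)
        e_width += w * (hi - lo)
    return float(e_map), float(e_lb), float(e_width)
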