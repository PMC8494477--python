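"""Prevalence as a function of effect-size threshold.

Instead of a single binarisation of each unit at a fixed significance
level, the per-unit effect statistic E_p is swept against a grid of
thresholds E.  At each threshold the false positive rate alpha(E) is the
null-tail probability of exceeding E, the count k(E) is the number of
units exceeding it, and (k, n, alpha) feed the standard single-group
posterior, yielding MAP and HPDI curves over the threshold grid.  All
units must share the same null distribution of the statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import stats

from .core import BetaPrior, PrevalencePosterior, TestResultCounts, map_estimate

__all__ = [
    "EffectSizeInputs",
    "EffectSizeCurve",
    "t_null_tail",
    "alpha_for_threshold",
    "prevalence_curve",
]

# thresholds whose alpha falls outside this window give a degenerate
# binomial model and are dropped from the curve
ALPHA_MIN = 1e-12
ALPHA_MAX = 1.0 - 1e-6

Tail = Literal["right", "left"]
NullTail = Callable[[np.ndarray], np.ndarray]
"""Maps threshold(s) to the *right*-tail probability P(E > threshold | null)."""


def t_null_tail(df: int) -> NullTail:
    """Analytic right-tail of the central t distribution with ``df`` degrees
    of freedom — the null of a within-unit one-sample t statistic."""
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")

    def tail(threshold):
        return stats.t.sf(threshold, df)

    return tail


@dataclass(frozen=True)
class EffectSizeInputs:
    """Per-unit effect statistics plus their common null distribution."""

    effects: np.ndarray
    null_tail: NullTail
    tail: Tail = "right"

    def __post_init__(self) -> None:
        eff = np.asarray(self.effects, dtype=float)
        if eff.ndim != 1 or len(eff) == 0:
            raise ValueError("effects must be a non-empty 1-d array")
        if not np.all(np.isfinite(eff)):
            raise ValueError("effects must be finite")
        if self.tail not in ("right", "left"):
            raise ValueError(f"tail must be 'right' or 'left', got {self.tail!r}")
        object.__setattr__(self, "effects", eff)


@dataclass(frozen=True)
class EffectSizeCurve:
    """Per-threshold counts, false positive rates and posterior summaries."""

    thresholds: np.ndarray
    alpha_at: np.ndarray
    k_at: np.ndarray
    map: np.ndarray
    hpdi_lo: np.ndarray
    hpdi_hi: np.ndarray
    hpdi_mass: float
    tail: Tail
    n: int


def alpha_for_threshold(null_tail: NullTail, threshold: float, tail: Tail = "right") -> float:
    """False positive rate of the threshold test E_p > threshold (or <).

    Right tail gives P(E > threshold | null); left tail P(E < threshold |
    null) = 1 - right tail (the null is continuous, so ties carry no mass).
    """
    if not np.isfinite(threshold):
        raise ValueError(f"threshold must be finite, got {threshold}")
    right = float(null_tail(np.asarray(threshold, dtype=float)))
    return right if tail == "right" else 1.0 - right


def prevalence_curve(
    inputs: EffectSizeInputs,
    n_thresholds: int = 200,
    mass: float = 0.96,
    prior: BetaPrior | None = None,
) -> EffectSizeCurve:
    """Posterior prevalence of units exceeding each threshold on a grid.

    Thresholds are linearly spaced over the observed range of the sample.
    Units tied exactly with a threshold count as not exceeding (strict
    inequality).  Grid points with a degenerate false positive rate
    (alpha outside (0, 1) to within numeric guard bands) are dropped with
    a warning, since the binomial prevalence model requires 0 < alpha < 1.
    """
    if n_thresholds < 2:
        raise ValueError(f"need at least 2 thresholds, got {n_thresholds}")
    eff = inputs.effects
    n = len(eff)
    grid = np.linspace(eff.min(), eff.max(), n_thresholds)

    rows = []
    for thr in grid:
        a = alpha_for_threshold(inputs.null_tail, float(thr), inputs.tail)
        if not ALPHA_MIN < a < ALPHA_MAX:
            continue
        k = int(np.sum(eff > thr)) if inputs.tail == "right" else int(np.sum(eff < thr))
        rows.append((float(thr), a, k))
    if not rows:
        raise ValueError("every grid threshold gave a degenerate false positive rate")
    if len(rows) < n_thresholds:
        warnings.warn(
            f"dropped {n_thresholds - len(rows)} threshold(s) with degenerate "
            "false positive rate",
            stacklevel=2,
        )

    maps, los, his = [], [], []
    for _, a, k in rows:
        counts = TestResultCounts(k, n, a)
        post = PrevalencePosterior(counts, prior or BetaPrior())
        lo, hi = post.hpdi(mass)
        maps.append(map_estimate(counts, prior))
        los.append(lo)
        his.append(hi)

    thr, a_at, k_at = (np.array(c) for c in zip(*rows))
    return EffectSizeCurve(
        thresholds=thr,
        alpha_at=a_at,
        k_at=k_at.astype(int),
        map=np.array(maps),
        hpdi_lo=np.array(los),
        hpdi_hi=np.array(his),
        hpdi_mass=mass,
        tail=inputs.tail,
        n=n,
    )
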