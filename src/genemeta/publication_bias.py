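"""Publication-bias diagnostics: funnel data, Egger's test, trim-and-fill.

Egger's regression test fits ordinary least squares of the standardized
effect t_i = log_or_i / se_i on the precision 1/se_i; funnel asymmetry shows
up as an intercept different from zero, tested with a t statistic on k - 2
degrees of freedom.

Duval & Tweedie's trim-and-fill iteratively estimates the number k0 of
studies missing from one side of the funnel via signed-rank statistics (L0
or R0), trims the k0 most extreme observed studies, re-pools, and finally
imputes k0 mirror-image studies to give a bias-adjusted pooled estimate.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .effect_pooling import (
    EffectEstimate,
    PooledResult,
    pool_fixed_iv,
    pool_random_dl,
)
from .errors import ConvergenceError, InsufficientStudiesError, SingularDesignError

__all__ = [
    "EggerResult",
    "FunnelPoint",
    "FunnelData",
    "TrimFillResult",
    "RankEstimator",
    "FunnelSide",
    "egger_test",
    "funnel_data",
    "trim_and_fill",
]


@dataclass(frozen=True)
class EggerResult:
    """Egger regression intercept (bias coefficient) and its t test."""

    intercept: float
    se_intercept: float
    slope: float
    df: int

    @property
    def t(self) -> float:
        # perfect fit (zero residuals): a zero intercept carries no evidence
        # of asymmetry, a nonzero one is unambiguous
        if self.se_intercept == 0.0:
            return 0.0 if self.intercept == 0.0 else math.copysign(math.inf,
                                                                   self.intercept)
        return self.intercept / self.se_intercept

    @property
    def p(self) -> float:
        return float(2.0 * stats.t.sf(abs(self.t), self.df))


@dataclass(frozen=True)
class FunnelPoint:
    """One study's funnel coordinates: x = log OR, y = SE of log OR."""

    study_label: str
    x: float
    y: float


@dataclass(frozen=True)
class FunnelData:
    """Funnel points plus pseudo-95%-CI guide lines around the pooled centre.

    ``guide_x_low`` / ``guide_x_high`` give, for each SE in ``guide_y``, the
    x positions of centre -/+ 1.959964 * SE. Rendered with the SE axis
    increasing downward.
    """

    points: tuple[FunnelPoint, ...]
    centre: float
    guide_y: tuple[float, ...]
    guide_x_low: tuple[float, ...]
    guide_x_high: tuple[float, ...]


class RankEstimator(str, enum.Enum):
    L0 = "L0"
    R0 = "R0"


class FunnelSide(str, enum.Enum):
    AUTO = "auto"
    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class TrimFillResult:
    """Trim-and-fill outcome: k0 imputed studies and the adjusted pooling."""

    k0: int
    side: FunnelSide
    adjusted: PooledResult
    adjusted_random: PooledResult
    imputed: tuple[EffectEstimate, ...]
    iterations: int


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Classical (unweighted) Egger regression of standardized effect on
    precision; returns the intercept test.
    """
    effects = list(effects)
    if len(effects) < 3:
        raise InsufficientStudiesError("Egger's test needs k >= 3 studies")
    precision = np.array([1.0 / e.se for e in effects])
    standardized = np.array([e.log_or / e.se for e in effects])
    if np.ptp(precision) == 0:
        raise SingularDesignError(
            "all studies have equal precision; Egger design is singular"
        )
    fit = stats.linregress(precision, standardized)
    return EggerResult(intercept=float(fit.intercept),
                       se_intercept=float(fit.intercept_stderr),
                       slope=float(fit.slope),
                       df=len(effects) - 2)


def funnel_data(effects: Sequence[EffectEstimate],
                pooled: PooledResult,
                n_guide: int = 50) -> FunnelData:
    """Funnel coordinates: one point per study plus pseudo-CI guide lines
    at pooled log OR +/- 1.959964 * SE over the observed SE range
    (extended down to SE = 0 so the funnel closes at the top).
    """
    effects = list(effects)
    if not effects:
        raise InsufficientStudiesError("funnel data needs k >= 1 studies")
    points = tuple(FunnelPoint(e.study_label, e.log_or, e.se) for e in effects)
    z = 1.959964
    se_max = max(e.se for e in effects)
    guide_y = tuple(np.linspace(0.0, se_max, n_guide))
    centre = pooled.pooled_log_or
    return FunnelData(
        points=points,
        centre=centre,
        guide_y=guide_y,
        guide_x_low=tuple(centre - z * y for y in guide_y),
        guide_x_high=tuple(centre + z * y for y in guide_y),
    )


def _estimate_k0(deviations: np.ndarray, estimator: RankEstimator) -> int:
    """Estimate the missing-study count from signed deviations (positive =
    the heavy, over-represented side).

    Ranks |deviation|; L0 = (4*Tn - n(n+1)) / (2n - 1) with Tn the rank sum
    of the positive deviations (Wilcoxon); R0 = (length of the rightmost
    run of positive-deviation ranks) - 1.
    """
    n = len(deviations)
    ranks = stats.rankdata(np.abs(deviations))
    positive = deviations > 0
    if estimator is RankEstimator.L0:
        t_n = ranks[positive].sum()
        k0 = (4.0 * t_n - n * (n + 1)) / (2.0 * n - 1.0)
        return max(0, int(round(k0)))
    # R0: walk down from the largest |deviation|; count consecutive positives
    order = np.argsort(-ranks)
    run = 0
    for idx in order:
        if positive[idx]:
            run += 1
        else:
            break
    return max(0, run - 1)


def trim_and_fill(effects: Sequence[EffectEstimate],
                  estimator: RankEstimator = RankEstimator.L0,
                  side: FunnelSide = FunnelSide.AUTO,
                  max_iter: int = 20) -> TrimFillResult:
    """Duval-Tweedie trim-and-fill with fixed-IV pooling inside the loop.

    ``side`` names the heavy (over-represented) side of the funnel from
    which extreme studies are trimmed; ``auto`` picks it from the sign of
    the Egger intercept. Imputed studies are mirror images of the trimmed
    extremes about the trimmed pooled value, with variances copied. The
    adjusted estimate is reported under both fixed and random models.
    """
    effects = list(effects)
    estimator = RankEstimator(estimator)
    side = FunnelSide(side)
    if len(effects) < 3:
        raise InsufficientStudiesError("trim-and-fill needs k >= 3 studies")

    if side is FunnelSide.AUTO:
        try:
            indicator = egger_test(effects).intercept
        except SingularDesignError:
            # equal precisions: fall back to the sign of the summed
            # deviations from the fixed-effects centre
            centre = pool_fixed_iv(effects).pooled_log_or
            indicator = float(sum(e.log_or - centre for e in effects))
        side = FunnelSide.RIGHT if indicator >= 0 else FunnelSide.LEFT
    sign = 1.0 if side is FunnelSide.RIGHT else -1.0

    log_ors = np.array([e.log_or for e in effects])
    order = np.argsort(sign * log_ors)  # ascending; heavy-side extremes last
    ordered = [effects[i] for i in order]

    k0 = 0
    for iteration in range(1, max_iter + 1):
        retained = ordered[:len(ordered) - k0] if k0 else ordered
        centre = pool_fixed_iv(retained).pooled_log_or
        deviations = sign * (np.array([e.log_or for e in ordered]) - centre)
        k0_new = _estimate_k0(deviations, estimator)
        k0_new = min(k0_new, len(ordered) - 2)  # keep >= 2 studies untrimmed
        if k0_new == k0:
            break
        k0 = k0_new
    else:
        raise ConvergenceError(
            f"trim-and-fill did not stabilise within {max_iter} iterations"
        )

    retained = ordered[:len(ordered) - k0] if k0 else ordered
    centre = pool_fixed_iv(retained).pooled_log_or
    imputed = tuple(
        EffectEstimate(study_label=f"imputed:{e.study_label}",
                       log_or=2.0 * centre - e.log_or,
                       var=e.var)
        for e in ordered[len(ordered) - k0:]
    )
    augmented = list(effects) + list(imputed)
    return TrimFillResult(
        k0=k0,
        side=side,
        adjusted=pool_fixed_iv(augmented),
        adjusted_random=pool_random_dl(augmented),
        imputed=imputed,
        iterations=iteration,
    )
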