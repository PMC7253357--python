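"""Per-study odds ratios and fixed/random-effects pooling.

The computational core: Woolf log-odds-ratio estimates per 2x2 table,
inverse-variance and Mantel-Haenszel fixed-effects pooling, DerSimonian-Laird
random effects, and Cochran's Q / I-squared heterogeneity.

Conventions
-----------
* Everything is pooled on the natural-log OR scale.
* 95% CIs use the exact normal quantile 1.959964.
* Two-sided P values come from the standard normal (Z test on the pooled
  log OR) or chi-square (Q) tails.
* I-squared = max(0, 100 * (Q - df) / Q), truncated at zero.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import (
    DegenerateInputError,
    InsufficientStudiesError,
    UndefinedRatioError,
    ZeroCellError,
)
from .genetic_models import TwoByTwoTable

__all__ = [
    "CorrectionPolicy",
    "PoolingModel",
    "EffectEstimate",
    "PooledResult",
    "HeterogeneityResult",
    "study_effect",
    "pool",
    "pool_fixed_iv",
    "pool_fixed_mh",
    "pool_random_dl",
    "heterogeneity",
]

Z_95 = 1.959964  # exact-to-6-figures normal 97.5% quantile


class CorrectionPolicy(str, enum.Enum):
    """Continuity-correction policy for zero cells."""

    NONE = "none"
    ADD_HALF_IF_ZERO = "add_half_if_zero"
    ALWAYS_HALF = "always_half"


class PoolingModel(str, enum.Enum):
    FIXED_IV = "fixed_iv"
    FIXED_MH = "fixed_mh"
    RANDOM_DL = "random_dl"


@dataclass(frozen=True)
class EffectEstimate:
    """One study's log odds ratio with Woolf variance and 95% CI (OR scale)."""

    study_label: str
    log_or: float
    var: float

    @property
    def se(self) -> float:
        return math.sqrt(self.var)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_or - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_or + Z_95 * self.se)


@dataclass(frozen=True)
class PooledResult:
    """A pooled log OR with its SE and derived OR-scale summaries."""

    model: PoolingModel
    k: int
    pooled_log_or: float
    se: float
    tau2: float = 0.0

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.pooled_log_or)

    # `or_` mirrors the conventional symbol OR while staying a valid name
    or_ = odds_ratio

    @property
    def ci_low(self) -> float:
        return math.exp(self.pooled_log_or - Z_95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.pooled_log_or + Z_95 * self.se)

    @property
    def z(self) -> float:
        return self.pooled_log_or / self.se

    @property
    def p(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q with its chi-square P and the derived I-squared percent."""

    q: float
    df: int

    @property
    def p_q(self) -> float:
        return float(stats.chi2.sf(self.q, self.df))

    @property
    def i2(self) -> float:
        if self.q <= 0:
            return 0.0
        return max(0.0, 100.0 * (self.q - self.df) / self.q)


def study_effect(table: TwoByTwoTable,
                 correction_policy: CorrectionPolicy = CorrectionPolicy.ADD_HALF_IF_ZERO,
                 ) -> EffectEstimate:
    """Woolf estimate: log OR = ln(ad/bc), var = 1/a + 1/b + 1/c + 1/d.

    Under ``add_half_if_zero``, 0.5 is added to all four cells of a table
    containing any zero before both formulas; under ``always_half`` the
    correction is unconditional; under ``none`` a zero cell is an error.
    """
    correction_policy = CorrectionPolicy(correction_policy)
    if table.a + table.b == 0 or table.c + table.d == 0:
        raise DegenerateInputError(
            f"table {table.label!r}: an arm has zero total; OR undefined"
        )
    if correction_policy is CorrectionPolicy.ALWAYS_HALF:
        table = table.with_half_correction()
    elif correction_policy is CorrectionPolicy.ADD_HALF_IF_ZERO and table.has_zero_cell():
        table = table.with_half_correction()
    elif correction_policy is CorrectionPolicy.NONE and table.has_zero_cell():
        raise ZeroCellError(
            f"table {table.label!r} has a zero cell and correction policy is 'none'"
        )
    a, b, c, d = table.cells()
    log_or = math.log(a * d / (b * c))
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectEstimate(study_label=table.label, log_or=log_or, var=var)


def _as_arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    log_ors = np.array([e.log_or for e in effects], dtype=float)
    variances = np.array([e.var for e in effects], dtype=float)
    return log_ors, variances


def pool_fixed_iv(effects: Sequence[EffectEstimate]) -> PooledResult:
    """Inverse-variance (Woolf-weighted) fixed-effects pooling."""
    effects = list(effects)
    if not effects:
        raise InsufficientStudiesError("fixed-effects pooling needs k >= 1 studies")
    log_ors, variances = _as_arrays(effects)
    weights = 1.0 / variances
    pooled = float((weights * log_ors).sum() / weights.sum())
    se = float(weights.sum() ** -0.5)
    return PooledResult(model=PoolingModel.FIXED_IV, k=len(effects),
                        pooled_log_or=pooled, se=se)


def pool_fixed_mh(tables: Sequence[TwoByTwoTable]) -> PooledResult:
    """Mantel-Haenszel fixed-effects pooled OR with the
    Robins-Breslow-Greenland variance for its log.
    """
    tables = list(tables)
    if not tables:
        raise InsufficientStudiesError("MH pooling needs k >= 1 tables")
    a = np.array([t.a for t in tables], dtype=float)
    b = np.array([t.b for t in tables], dtype=float)
    c = np.array([t.c for t in tables], dtype=float)
    d = np.array([t.d for t in tables], dtype=float)
    n = a + b + c + d
    if np.any(n == 0):
        raise DegenerateInputError("a stratum has zero total")
    r = a * d / n           # per-stratum numerator terms
    s = b * c / n           # per-stratum denominator terms
    r_sum, s_sum = r.sum(), s.sum()
    if s_sum == 0:
        raise UndefinedRatioError("sum of b*c/n is zero; MH odds ratio undefined")
    or_mh = r_sum / s_sum
    # Robins-Breslow-Greenland variance of ln(OR_MH)
    p = (a + d) / n
    q = (b + c) / n
    var = (float((p * r).sum()) / (2 * r_sum ** 2)
           + float((p * s + q * r).sum()) / (2 * r_sum * s_sum)
           + float((q * s).sum()) / (2 * s_sum ** 2))
    return PooledResult(model=PoolingModel.FIXED_MH, k=len(tables),
                        pooled_log_or=math.log(or_mh), se=math.sqrt(var))


def heterogeneity(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q about the fixed-IV pooled value, df = k - 1."""
    effects = list(effects)
    if len(effects) < 2:
        raise InsufficientStudiesError("heterogeneity needs k >= 2 studies")
    log_ors, variances = _as_arrays(effects)
    weights = 1.0 / variances
    pooled = (weights * log_ors).sum() / weights.sum()
    q = float((weights * (log_ors - pooled) ** 2).sum())
    return HeterogeneityResult(q=q, df=len(effects) - 1)


def dl_tau_squared(effects: Sequence[EffectEstimate]) -> float:
    """DerSimonian-Laird moment estimator of between-study variance,
    truncated at zero."""
    log_ors, variances = _as_arrays(list(effects))
    weights = 1.0 / variances
    pooled = (weights * log_ors).sum() / weights.sum()
    q = (weights * (log_ors - pooled) ** 2).sum()
    df = len(log_ors) - 1
    denom = weights.sum() - (weights ** 2).sum() / weights.sum()
    return float(max(0.0, (q - df) / denom))


def pool_random_dl(effects: Sequence[EffectEstimate]) -> PooledResult:
    """DerSimonian-Laird random-effects pooling.

    Equals the fixed-IV result exactly whenever Q <= df (tau^2 truncates
    to zero).
    """
    effects = list(effects)
    if len(effects) < 2:
        raise InsufficientStudiesError("random-effects pooling needs k >= 2 studies")
    tau2 = dl_tau_squared(effects)
    log_ors, variances = _as_arrays(effects)
    weights = 1.0 / (variances + tau2)
    pooled = float((weights * log_ors).sum() / weights.sum())
    se = float(weights.sum() ** -0.5)
    return PooledResult(model=PoolingModel.RANDOM_DL, k=len(effects),
                        pooled_log_or=pooled, se=se, tau2=tau2)


def pool(effects: Sequence[EffectEstimate],
         model: PoolingModel = PoolingModel.FIXED_IV,
         tables: Sequence[TwoByTwoTable] | None = None) -> PooledResult:
    """Dispatch to the requested pooling model.

    ``fixed_mh`` needs the original 2x2 tables; the other models pool
    effect estimates.
    """
    model = PoolingModel(model)
    if model is PoolingModel.FIXED_IV:
        return pool_fixed_iv(effects)
    if model is PoolingModel.RANDOM_DL:
        return pool_random_dl(effects)
    if tables is None:
        raise ValueError("Mantel-Haenszel pooling requires the 2x2 tables")
    return pool_fixed_mh(tables)
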