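"""Genetic-model collapses of genotype counts and Hardy-Weinberg testing.

A biallelic genotype triple (Val/Val, Val/Met, Met/Met) is collapsed into an
exposure x outcome 2x2 table under a genetic model:

* dominant  — Val/* carriers (Val/Val + Val/Met) vs Met/Met
* recessive — Val/Val vs Met/* (Val/Met + Met/Met)
* allelic   — Val alleles vs Met alleles (each subject contributes two)
* additive  — no single 2x2 collapse; realised as a Cochran-Armitage trend
  test with Val-dose scores 0/1/2

Exposure is always the Val-containing category and cases are always the
first (smoking-persistent) arm, so OR > 1 means Val carriers maintain
smoking more.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, UnavailableContrastError, UnsupportedModelError
from .study_data import GenotypeArm, StudyRecord

__all__ = [
    "GeneticModel",
    "PhenotypeContrast",
    "TwoByTwoTable",
    "HweResult",
    "TrendResult",
    "build_contingency",
    "cochran_armitage_trend",
    "hwe_chi_square",
    "val_star_frequency",
]


class GeneticModel(str, enum.Enum):
    """How genotypes map to an exposure dichotomy. Dominant is the default."""

    DOMINANT = "dominant"
    RECESSIVE = "recessive"
    ALLELIC = "allelic"
    ADDITIVE = "additive"


class PhenotypeContrast(str, enum.Enum):
    """Which smoking-status arms form cases and controls (case arm first)."""

    PERSISTENCE = "persistence"  # current vs never
    INITIATION = "initiation"    # ever vs never
    CESSATION = "cessation"      # current vs former

    @property
    def arms(self) -> tuple[str, str]:
        return _CONTRAST_ARMS[self]


_CONTRAST_ARMS = {
    PhenotypeContrast.PERSISTENCE: ("current", "never"),
    PhenotypeContrast.INITIATION: ("ever", "never"),
    PhenotypeContrast.CESSATION: ("current", "former"),
}


@dataclass(frozen=True)
class TwoByTwoTable:
    """Exposure x outcome counts: a = cases exposed, b = cases unexposed,
    c = controls exposed, d = controls unexposed.

    ``corrected`` flags a 0.5 continuity correction (cells then half-integers).
    """

    a: float
    b: float
    c: float
    d: float
    corrected: bool = False
    label: str = ""

    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    def has_zero_cell(self) -> bool:
        return any(cell == 0 for cell in self.cells())

    def with_half_correction(self) -> "TwoByTwoTable":
        return TwoByTwoTable(self.a + 0.5, self.b + 0.5, self.c + 0.5,
                             self.d + 0.5, corrected=True, label=self.label)


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg goodness-of-fit on one arm (1 df chi-square)."""

    chi2: float
    p: float
    allele_freq: float
    monomorphic: bool = False


@dataclass(frozen=True)
class TrendResult:
    """Cochran-Armitage trend statistic (1 df) on a 2x3 genotype table."""

    chi2: float
    p: float


def _arms_for(record: StudyRecord,
              contrast: PhenotypeContrast) -> tuple[GenotypeArm, GenotypeArm]:
    case_name, control_name = contrast.arms
    case = record.arm(case_name)
    control = record.arm(control_name)
    if case is None or control is None:
        missing = case_name if case is None else control_name
        raise UnavailableContrastError(
            f"study {record.label!r} has no {missing!r} arm; "
            f"contrast {contrast.value!r} unavailable"
        )
    return case, control


def build_contingency(record: StudyRecord,
                      model: GeneticModel = GeneticModel.DOMINANT,
                      contrast: PhenotypeContrast = PhenotypeContrast.PERSISTENCE,
                      ) -> TwoByTwoTable:
    """Collapse a study record into a 2x2 table under a genetic model.

    The additive model has no 2x2 collapse and raises
    :class:`UnsupportedModelError` pointing at
    :func:`cochran_armitage_trend`.
    """
    model = GeneticModel(model)
    contrast = PhenotypeContrast(contrast)
    case, control = _arms_for(record, contrast)
    if model is GeneticModel.DOMINANT:
        cells = (case.vv + case.vm, case.mm, control.vv + control.vm, control.mm)
    elif model is GeneticModel.RECESSIVE:
        cells = (case.vv, case.vm + case.mm, control.vv, control.vm + control.mm)
    elif model is GeneticModel.ALLELIC:
        cells = (2 * case.vv + case.vm, 2 * case.mm + case.vm,
                 2 * control.vv + control.vm, 2 * control.mm + control.vm)
    else:
        raise UnsupportedModelError(
            "additive model has no single 2x2 collapse; "
            "use cochran_armitage_trend for the per-genotype trend test"
        )
    return TwoByTwoTable(*map(float, cells), label=record.label)


def cochran_armitage_trend(record: StudyRecord,
                           contrast: PhenotypeContrast = PhenotypeContrast.PERSISTENCE,
                           ) -> TrendResult:
    """Cochran-Armitage trend test with Val-dose scores Met/Met=0,
    Val/Met=1, Val/Val=2 — the additive-model analysis of a 2x3 table.

    The statistic is N times the squared correlation between case status
    and genotype score, referred to chi-square with 1 df.
    """
    case, control = _arms_for(record, contrast)
    if case.total() == 0 or control.total() == 0:
        raise DegenerateInputError(
            f"study {record.label!r}: an arm of contrast {contrast.value!r} "
            "has zero total"
        )
    # rows: cases, controls; columns ordered by score 0,1,2
    counts = np.array([[case.mm, case.vm, case.vv],
                       [control.mm, control.vm, control.vv]], dtype=float)
    scores = np.array([0.0, 1.0, 2.0])
    n = counts.sum()
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    # correlation between score and case indicator over the N subjects
    mean_s = (col * scores).sum() / n
    var_s = (col * (scores - mean_s) ** 2).sum() / n
    p_case = row[0] / n
    var_y = p_case * (1 - p_case)
    # cov(score, case indicator) = E[s*y] - E[s]E[y]
    cov = (counts[0] * scores).sum() / n - mean_s * p_case
    if var_s == 0 or var_y == 0:
        return TrendResult(chi2=0.0, p=1.0)
    r2 = cov ** 2 / (var_s * var_y)
    chi2 = n * r2
    return TrendResult(chi2=float(chi2), p=float(stats.chi2.sf(chi2, 1)))


def hwe_chi_square(arm: GenotypeArm) -> HweResult:
    """Pearson chi-square test of Hardy-Weinberg proportions (1 df).

    The Val-allele frequency is estimated as p = (2*vv + vm) / (2*total);
    expected genotype counts are (p^2, 2p(1-p), (1-p)^2) * total. A
    monomorphic arm (p in {0, 1}) is flagged and returns chi2 = 0, p = 1.
    """
    total = arm.total()
    if total == 0:
        raise DegenerateInputError("cannot test HWE on an arm with zero total")
    p_hat = (2 * arm.vv + arm.vm) / (2 * total)
    if p_hat in (0.0, 1.0):
        return HweResult(chi2=0.0, p=1.0, allele_freq=p_hat, monomorphic=True)
    expected = np.array([p_hat ** 2, 2 * p_hat * (1 - p_hat),
                         (1 - p_hat) ** 2]) * total
    observed = np.array(arm.as_tuple(), dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HweResult(chi2=chi2, p=float(stats.chi2.sf(chi2, 1)),
                     allele_freq=p_hat)


def val_star_frequency(record: StudyRecord) -> float:
    """Percent of Val/* (Val-carrier) genotypes across both persistence
    arms, reported to one decimal — the Val/* genotype frequency column of
    a study-characteristics table.
    """
    case, control = _arms_for(record, PhenotypeContrast.PERSISTENCE)
    total = case.total() + control.total()
    if total == 0:
        raise DegenerateInputError(
            f"study {record.label!r}: zero total, Val/* frequency undefined"
        )
    carriers = case.vv + case.vm + control.vv + control.vm
    return round(100.0 * carriers / total, 1)
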