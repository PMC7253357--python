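"""Robustness checks: leave-one-out sensitivity and cumulative-by-year
meta-analysis.

Leave-one-out re-pools the remaining k-1 studies after omitting each study
in turn; a finding is robust when every row stays significant and the pooled
OR moves little. The cumulative analysis orders studies by publication year
and pools every prefix, showing how the evidence evolved; studies sharing a
year enter together (one row per distinct year).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .effect_pooling import (
    CorrectionPolicy,
    EffectEstimate,
    PooledResult,
    PoolingModel,
    pool,
    study_effect,
)
from .errors import InsufficientStudiesError, MetadataError
from .genetic_models import (
    GeneticModel,
    PhenotypeContrast,
    TwoByTwoTable,
    build_contingency,
)
from .study_data import StudySet

__all__ = ["SensitivityRow", "CumulativeRow", "leave_one_out", "cumulative_by_year"]


@dataclass(frozen=True)
class SensitivityRow:
    omitted_label: str
    pooled: PooledResult


@dataclass(frozen=True)
class CumulativeRow:
    through_year: int
    labels_included: tuple[str, ...]
    pooled: PooledResult


def _tables_and_effects(
    studies: StudySet,
    model: GeneticModel,
    contrast: PhenotypeContrast,
    correction: CorrectionPolicy,
) -> tuple[list[TwoByTwoTable], list[EffectEstimate]]:
    tables = [build_contingency(s, model, contrast) for s in studies]
    effects = [study_effect(t, correction) for t in tables]
    return tables, effects


def leave_one_out(studies: StudySet,
                  model: GeneticModel = GeneticModel.DOMINANT,
                  contrast: PhenotypeContrast = PhenotypeContrast.PERSISTENCE,
                  pooling: PoolingModel = PoolingModel.FIXED_IV,
                  correction: CorrectionPolicy = CorrectionPolicy.ADD_HALF_IF_ZERO,
                  ) -> list[SensitivityRow]:
    """One row per study: the pooled result over the other k-1 studies."""
    if len(studies) < 3:
        raise InsufficientStudiesError("leave-one-out needs k >= 3 studies")
    tables, effects = _tables_and_effects(studies, model, contrast, correction)
    rows = []
    for i, study in enumerate(studies):
        rest_effects = effects[:i] + effects[i + 1:]
        rest_tables = tables[:i] + tables[i + 1:]
        rows.append(SensitivityRow(
            omitted_label=study.label,
            pooled=pool(rest_effects, pooling, tables=rest_tables),
        ))
    return rows


def cumulative_by_year(studies: StudySet,
                       model: GeneticModel = GeneticModel.DOMINANT,
                       contrast: PhenotypeContrast = PhenotypeContrast.PERSISTENCE,
                       pooling: PoolingModel = PoolingModel.FIXED_IV,
                       correction: CorrectionPolicy = CorrectionPolicy.ADD_HALF_IF_ZERO,
                       ) -> list[CumulativeRow]:
    """One row per distinct publication year, pooling all studies published
    in or before that year. Studies are ordered by (year, label); the final
    row equals the all-studies pooled result.
    """
    if len(studies) < 1:
        raise InsufficientStudiesError("cumulative analysis needs k >= 1 studies")
    for s in studies:
        if s.year is None:
            raise MetadataError(f"study {s.label!r} has no publication year")
    ordered = sorted(studies, key=lambda s: (s.year, s.label))
    years = sorted({s.year for s in ordered})
    rows = []
    for year in years:
        included = [s for s in ordered if s.year <= year]
        subset = StudySet(included, provenance=f"through {year}")
        tables, effects = _tables_and_effects(subset, model, contrast, correction)
        rows.append(CumulativeRow(
            through_year=year,
            labels_included=tuple(s.label for s in included),
            pooled=pool(effects, pooling, tables=tables),
        ))
    return rows
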