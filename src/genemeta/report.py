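"""Pipeline runner and report assembly.

`run_pipeline` ties the modules together: build 2x2 tables under the
configured genetic model and contrast, estimate per-study effects, pool
under the requested models, quantify heterogeneity, run publication-bias
diagnostics, and produce sensitivity/cumulative tables — for the full study
set and for each ancestry subgroup meeting the minimum-cohort rule.

All numbers are serialised at full precision in the JSON report; display
rounding (2 decimals for ORs, 1 for I-squared) happens only in text and
plot rendering.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from .effect_pooling import (
    CorrectionPolicy,
    EffectEstimate,
    HeterogeneityResult,
    PooledResult,
    PoolingModel,
    heterogeneity,
    pool,
    study_effect,
)
from .errors import InsufficientStudiesError, PipelineError, UnavailableContrastError
from .genetic_models import (
    GeneticModel,
    PhenotypeContrast,
    build_contingency,
    hwe_chi_square,
    val_star_frequency,
)
from .publication_bias import egger_test, trim_and_fill
from .robustness import cumulative_by_year, leave_one_out
from .study_data import StudySet, load_fixture, read_studies

logger = logging.getLogger("genemeta")

__all__ = ["AnalysisConfig", "Report", "run_pipeline", "report_to_json"]


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    input_path: Optional[str] = None
    use_fixture: bool = False
    model: GeneticModel = GeneticModel.DOMINANT
    contrast: PhenotypeContrast = PhenotypeContrast.PERSISTENCE
    pooling_models: tuple[PoolingModel, ...] = (
        PoolingModel.FIXED_IV, PoolingModel.FIXED_MH, PoolingModel.RANDOM_DL,
    )
    subgroup: Optional[str] = "ancestry"
    min_subgroup_cohorts: int = 2
    correction: CorrectionPolicy = CorrectionPolicy.ADD_HALF_IF_ZERO
    output_dir: Optional[str] = None
    seed: int = 0


@dataclass
class AnalysisSection:
    """One analysis (overall or a subgroup): effects, poolings, diagnostics."""

    name: str
    labels: tuple[str, ...]
    n_participants: int
    effects: list[EffectEstimate]
    pooled: dict[str, PooledResult]
    het: Optional[HeterogeneityResult]
    egger: Optional[object]
    trim_fill: Optional[object]


@dataclass
class Report:
    config: AnalysisConfig
    sections: dict[str, AnalysisSection]
    per_study: list[dict]
    sensitivity: list
    cumulative: list
    skipped_subgroups: list[str] = field(default_factory=list)
    version: str = __version__


def _analyse(name: str, studies: StudySet, config: AnalysisConfig) -> AnalysisSection:
    tables = [build_contingency(s, config.model, config.contrast) for s in studies]
    effects = [study_effect(t, config.correction) for t in tables]
    pooled = {}
    for model in config.pooling_models:
        try:
            pooled[model.value] = pool(effects, model, tables=tables)
        except InsufficientStudiesError as exc:
            logger.info("section %s: %s pooling skipped (%s)", name, model.value, exc)
    het = heterogeneity(effects) if len(effects) >= 2 else None
    egger = None
    tf = None
    if len(effects) >= 3:
        egger = egger_test(effects)
        tf = trim_and_fill(effects)
    return AnalysisSection(
        name=name,
        labels=tuple(s.label for s in studies),
        n_participants=studies.grand_total(),
        effects=effects,
        pooled=pooled,
        het=het,
        egger=egger,
        trim_fill=tf,
    )


def run_pipeline(config: AnalysisConfig,
                 studies: Optional[StudySet] = None) -> Report:
    """Run the full meta-analysis pipeline.

    Studies come from ``config.input_path``, the packaged fixture, or an
    in-memory ``studies`` argument. Subgroups with fewer cohorts than
    ``config.min_subgroup_cohorts`` are skipped with a logged notice.
    """
    if studies is None:
        if config.use_fixture:
            studies = load_fixture()
        elif config.input_path:
            studies = read_studies(config.input_path)
        else:
            raise PipelineError("no input: set input_path, use_fixture, or studies")
    if len(studies) == 0:
        raise PipelineError("study set is empty after loading")

    try:
        sections = {"overall": _analyse("overall", studies, config)}
    except UnavailableContrastError as exc:
        raise PipelineError(
            f"contrast {config.contrast.value!r} unavailable: {exc}"
        ) from exc

    skipped = []
    if config.subgroup == "ancestry":
        groups = {s.ancestry for s in studies}
        for ancestry in sorted(groups):
            subset = studies.filter(ancestry=ancestry)
            if len(subset) < config.min_subgroup_cohorts:
                logger.info("subgroup %s skipped: %d cohort(s) < minimum %d",
                            ancestry, len(subset), config.min_subgroup_cohorts)
                skipped.append(ancestry)
                continue
            sections[ancestry] = _analyse(ancestry, subset, config)

    per_study = []
    for study in studies:
        table = build_contingency(study, config.model, config.contrast)
        effect = study_effect(table, config.correction)
        hwe = hwe_chi_square(study.never)
        per_study.append({
            "label": study.label,
            "year": study.year,
            "ancestry": study.ancestry,
            "n": study.total(),
            "val_star_freq": val_star_frequency(study),
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "or": effect.odds_ratio,
            "ci_low": effect.ci_low,
            "ci_high": effect.ci_high,
            "log_or": effect.log_or,
            "se": effect.se,
            "hwe_control_chi2": hwe.chi2,
            "hwe_control_p": hwe.p,
        })

    loo_pooling = (PoolingModel.FIXED_IV
                   if PoolingModel.FIXED_IV in config.pooling_models
                   else config.pooling_models[0])
    sensitivity = (leave_one_out(studies, config.model, config.contrast,
                                 loo_pooling, config.correction)
                   if len(studies) >= 3 else [])
    cumulative = cumulative_by_year(studies, config.model, config.contrast,
                                    loo_pooling, config.correction)

    return Report(config=config, sections=sections, per_study=per_study,
                  sensitivity=sensitivity, cumulative=cumulative,
                  skipped_subgroups=skipped)


def _pooled_dict(result: PooledResult) -> dict:
    return {
        "model": result.model.value,
        "k": result.k,
        "pooled_log_or": result.pooled_log_or,
        "se": result.se,
        "or": result.odds_ratio,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "z": result.z,
        "p": result.p,
        "tau2": result.tau2,
    }


def report_to_dict(report: Report) -> dict:
    """Serialise a report to plain JSON-ready structures (full precision)."""
    out = {
        "version": report.version,
        "config": {
            "model": report.config.model.value,
            "contrast": report.config.contrast.value,
            "pooling_models": [m.value for m in report.config.pooling_models],
            "subgroup": report.config.subgroup,
            "min_subgroup_cohorts": report.config.min_subgroup_cohorts,
            "correction": report.config.correction.value,
            "seed": report.config.seed,
        },
        "per_study": report.per_study,
        "skipped_subgroups": report.skipped_subgroups,
        "sections": {},
        "sensitivity": [
            {"omitted": row.omitted_label, **_pooled_dict(row.pooled)}
            for row in report.sensitivity
        ],
        "cumulative": [
            {"through_year": row.through_year,
             "labels": list(row.labels_included),
             **_pooled_dict(row.pooled)}
            for row in report.cumulative
        ],
    }
    for name, section in report.sections.items():
        entry = {
            "labels": list(section.labels),
            "n_participants": section.n_participants,
            "pooled": {m: _pooled_dict(r) for m, r in section.pooled.items()},
        }
        if section.het is not None:
            entry["heterogeneity"] = {
                "q": section.het.q, "df": section.het.df,
                "p_q": section.het.p_q, "i2": section.het.i2,
            }
        if section.egger is not None:
            entry["egger"] = {
                "intercept": section.egger.intercept,
                "se_intercept": section.egger.se_intercept,
                "t": section.egger.t,
                "df": section.egger.df,
                "p": section.egger.p,
            }
        if section.trim_fill is not None:
            entry["trim_and_fill"] = {
                "k0": section.trim_fill.k0,
                "side": section.trim_fill.side.value,
                "iterations": section.trim_fill.iterations,
                "adjusted_fixed": _pooled_dict(section.trim_fill.adjusted),
                "adjusted_random": _pooled_dict(section.trim_fill.adjusted_random),
            }
        out["sections"][name] = entry
    return out


def report_to_json(report: Report, path=None) -> str:
    """JSON text of the report; optionally written to ``path``.

    Deterministic for a given config and input (no timestamps inside the
    comparison surface).
    """
    text = json.dumps(report_to_dict(report), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def render_text(report: Report) -> str:
    """Human-readable summary with display rounding (ORs to 2 decimals,
    I-squared to 1)."""
    lines = [f"genemeta {report.version} — genotype-count meta-analysis", ""]
    for name, section in report.sections.items():
        lines.append(f"[{name}] k={len(section.labels)} "
                     f"N={section.n_participants}")
        for model, res in section.pooled.items():
            lines.append(
                f"  {model:9s} OR={res.odds_ratio:.2f} "
                f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}) "
                f"Z={res.z:.2f} P={res.p:.3f}"
                + (f" tau2={res.tau2:.4f}" if res.model is PoolingModel.RANDOM_DL
                   else "")
            )
        if section.het is not None:
            lines.append(f"  heterogeneity Q={section.het.q:.2f} "
                         f"df={section.het.df} P_Q={section.het.p_q:.2f} "
                         f"I2={section.het.i2:.1f}")
        if section.egger is not None:
            lines.append(f"  Egger intercept={section.egger.intercept:.3f} "
                         f"P={section.egger.p:.2f}")
        if section.trim_fill is not None:
            adj = section.trim_fill.adjusted
            lines.append(f"  trim-and-fill k0={section.trim_fill.k0} "
                         f"adjusted OR={adj.odds_ratio:.2f} "
                         f"({adj.ci_low:.2f}-{adj.ci_high:.2f})")
        lines.append("")
    if report.skipped_subgroups:
        lines.append("skipped subgroups (below minimum cohorts): "
                     + ", ".join(report.skipped_subgroups))
    return "\n".join(lines)
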