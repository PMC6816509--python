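"""End-to-end orchestration: cohort -> scores -> fits -> IISD -> validity.

This module glues the stages together the way the full analysis runs
them: standardization moments come from the standardizing sample
(cognitively unimpaired, >= 2 visits), every outcome gets a
covariate-adjusted random-slopes fit, conditional residuals feed the
IISD stage, and the biomarker subsample feeds the criterion-validity
stage (scored with the standardizing sample's parameters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import pandas as pd

from .cohort import apply_inclusion_rules
from .composites import (
    CompositeDefinition,
    OUTCOME_COLUMNS,
    StandardizationParams,
    add_composites,
    apply_standardization,
    standardize,
    table2_registry,
)
from .inconsistency import IISDResult, compute_iisd, iisd_table, summarize_iisd
from .mtmm import MTMMMatrix, correlogram, mtmm_matrix
from .trajectory import ModelSpec, TrajectoryFit, fit_random_slopes, \
    prepare_model_frame, subject_slopes
from .validity import ValidityResult, abeta_interaction, abeta_two_stage, \
    biomarker_slope_correlation

__all__ = [
    "PipelineSettings",
    "SampleEvaluation",
    "EvaluationResult",
    "score_sample",
    "fit_outcomes",
    "run_iisd",
    "evaluate_sample",
    "evaluate_validity",
    "evaluate_cohort",
]

log = logging.getLogger(__name__)


@dataclass
class PipelineSettings:
    outcomes: list[str] = field(default_factory=lambda: list(OUTCOME_COLUMNS))
    registry: list[CompositeDefinition] = field(default_factory=table2_registry)
    exposures_coding: str = "categorical"
    residual_type: str = "conditional"
    n_boot: int = 1000
    seed: int = 0
    age_center: float | None = None


def score_sample(
    sample: pd.DataFrame,
    registry: list[CompositeDefinition],
    params: StandardizationParams | None = None,
) -> tuple[pd.DataFrame, StandardizationParams]:
    """Standardize and add composites.  With ``params`` given, the
    sample is scored on a previously fitted scale (held-out scoring);
    otherwise moments are estimated from the sample itself."""
    if params is None:
        z, params = standardize(sample)
        scores = add_composites(z, registry, params=params)
    else:
        z = apply_standardization(sample, params)
        scores = add_composites(z, registry, params=params)
    return scores, params


def fit_outcomes(
    scores: pd.DataFrame,
    sample: pd.DataFrame,
    settings: PipelineSettings,
    include_abeta: bool = False,
) -> dict[str, TrajectoryFit]:
    fits: dict[str, TrajectoryFit] = {}
    for outcome in settings.outcomes:
        frame = prepare_model_frame(scores, sample, outcome)
        spec = ModelSpec(
            outcome=outcome, include_abeta=include_abeta,
            exposures_coding=settings.exposures_coding,
            residual_type=settings.residual_type,
            age_center=settings.age_center,
        )
        fits[outcome] = fit_random_slopes(frame, spec)
    return fits


def run_iisd(
    fits: dict[str, TrajectoryFit], settings: PipelineSettings,
) -> list[IISDResult]:
    results = []
    for outcome, fit in fits.items():
        res = compute_iisd(fit.residuals, fit.diagnostics["subject_ids"],
                           outcome=outcome)
        summarize_iisd(res, n_boot=settings.n_boot, seed=settings.seed)
        results.append(res)
    return results


@dataclass
class SampleEvaluation:
    sample: pd.DataFrame
    scores: pd.DataFrame
    params: StandardizationParams
    fits: dict[str, TrajectoryFit]
    iisd: list[IISDResult]

    @property
    def iisd_table(self) -> pd.DataFrame:
        return iisd_table(self.iisd)

    def mean_iisd(self) -> pd.Series:
        return self.iisd_table["mean_iisd"]


def evaluate_sample(
    sample: pd.DataFrame,
    settings: PipelineSettings,
    params: StandardizationParams | None = None,
) -> SampleEvaluation:
    """Score a sample and run the trajectory + IISD stages."""
    scores, params = score_sample(sample, settings.registry, params)
    fits = fit_outcomes(scores, sample, settings)
    iisd = run_iisd(fits, settings)
    return SampleEvaluation(sample, scores, params, fits, iisd)


def evaluate_validity(
    biomarker_sample: pd.DataFrame,
    settings: PipelineSettings,
    params: StandardizationParams,
) -> ValidityResult:
    """Criterion-validity metrics on the biomarker subsample.

    Per outcome: stage-1 covariate-only fit (for two-stage residuals
    and subject slopes), two-stage generalized R^2, one-stage Ab x age
    interaction with Wald CI, and Spearman correlations between
    continuous biomarkers and subject slope estimates.
    """
    scores, _ = score_sample(biomarker_sample, settings.registry, params)
    subject_markers = (
        biomarker_sample.groupby("subject_id")[
            [c for c in ("pib_dvr", "csf_ab42", "csf_ab4240")
             if c in biomarker_sample.columns]
        ].first()
    )
    rows = {}
    details = {}
    for outcome in settings.outcomes:
        frame = prepare_model_frame(scores, biomarker_sample, outcome)
        stage1 = fit_random_slopes(frame, ModelSpec(
            outcome=outcome, exposures_coding=settings.exposures_coding,
            residual_type=settings.residual_type,
            age_center=settings.age_center,
        ))
        r2 = abeta_two_stage(stage1.residuals, frame, stage1.age_center)
        inter, full_fit = abeta_interaction(
            frame, outcome, exposures_coding=settings.exposures_coding,
            age_center=settings.age_center,
        )
        slopes = subject_slopes(stage1)
        rho = biomarker_slope_correlation(slopes, subject_markers)
        row = {
            "beta_age": full_fit.params.loc["age_c", "estimate"],
            "beta_age_ci_low": full_fit.params.loc["age_c", "ci_low"],
            "beta_age_ci_high": full_fit.params.loc["age_c", "ci_high"],
            "beta_interaction": inter["estimate"],
            "interaction_ci_low": inter["ci_low"],
            "interaction_ci_high": inter["ci_high"],
            "r2_glmm": r2["r2_marginal"],
            "r2_conditional": r2["r2_conditional"],
        }
        for marker, value in rho.items():
            row[f"rho_{marker}"] = value
        rows[outcome] = row
        details[outcome] = {"stage1": stage1, "full": full_fit, "r2": r2}
    table = pd.DataFrame(rows).T
    table.index.name = "outcome"
    return ValidityResult(table=table, details=details)


@dataclass
class EvaluationResult:
    standardizing: SampleEvaluation
    validity: ValidityResult | None
    correlogram: pd.DataFrame
    mtmm: MTMMMatrix
    settings: PipelineSettings

    def iisd_order(self) -> list[str]:
        tab = self.standardizing.iisd_table
        return list(tab.sort_values(["mean_iisd"]).index)


def evaluate_cohort(
    table: pd.DataFrame, settings: PipelineSettings | None = None,
) -> EvaluationResult:
    """Run the full analysis on a cohort table."""
    settings = replace(settings) if settings else PipelineSettings()
    std_sample = apply_inclusion_rules(table, "standardizing")
    if settings.age_center is None:
        settings.age_center = float(std_sample["age_at_visit"].mean())
    std_eval = evaluate_sample(std_sample, settings)

    validity = None
    bio_sample = apply_inclusion_rules(table, "biomarker")
    has_abeta = ("abeta_status" in bio_sample
                 and bio_sample["abeta_status"].nunique() == 2
                 and bio_sample["subject_id"].nunique() >= 20)
    if has_abeta:
        validity = evaluate_validity(bio_sample, settings, std_eval.params)
    else:
        log.warning("biomarker subsample unusable; skipping validity stage")

    scores_with_subject = std_eval.scores.copy()
    corr = correlogram(scores_with_subject, settings.outcomes)
    mtmm = mtmm_matrix(scores_with_subject)
    return EvaluationResult(
        standardizing=std_eval, validity=validity,
        correlogram=corr, mtmm=mtmm, settings=settings,
    )
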