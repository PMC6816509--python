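"""Robustness analyses.

Three checks of how fragile the main findings are to the exclusion of
clinically impaired participants: (1) mean IISD recomputed on the
expanded sample that re-admits impaired subjects, with the
impaired-minus-unimpaired IISD difference per outcome; (2) group mean
IISD for a set of risk groups versus a lower-risk comparison group;
(3) agreement of the criterion-validity metrics between biomarker
samples with and without impaired subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import apply_inclusion_rules
from .inconsistency import summarize_iisd
from .pipeline import PipelineSettings, evaluate_sample, evaluate_validity

__all__ = [
    "SensitivityReport",
    "expanded_sample_iisd",
    "risk_group_iisd",
    "validity_sensitivity",
]

log = logging.getLogger(__name__)

RISK_GROUPS = ["comparison", "apoe_e4", "psych_dx", "fair_poor_health",
               "clinical_dx"]


@dataclass
class SensitivityReport:
    iisd_by_sample: pd.DataFrame | None = None      # outcome x sample
    iisd_cross_sample_r: float | None = None
    delta_iisd: pd.Series | None = None             # impaired - unimpaired
    group_means: pd.DataFrame | None = None         # outcome x group
    group_cis: dict = field(default_factory=dict)
    group_contrasts: pd.DataFrame | None = None
    small_groups: list[str] = field(default_factory=list)
    agreement: pd.DataFrame | None = None           # metric x (pearson, spearman)
    notes: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        out = {"notes": self.notes}
        if self.iisd_by_sample is not None:
            out["iisd_by_sample"] = self.iisd_by_sample.to_dict()
            out["iisd_cross_sample_r"] = self.iisd_cross_sample_r
            out["delta_iisd"] = self.delta_iisd.to_dict()
        if self.group_means is not None:
            out["group_means"] = self.group_means.to_dict()
            out["group_contrasts"] = self.group_contrasts.to_dict()
            out["small_groups"] = self.small_groups
        if self.agreement is not None:
            out["agreement"] = self.agreement.to_dict()
        return out


def _subject_flags(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject risk-group flags (any-visit basis for clinical dx)."""
    agg = table.groupby("subject_id").agg(
        apoe_e4=("apoe_e4", "first"),
        psych_dx=("psych_dx", "first"),
        fair_poor_health=("fair_poor_health", "first"),
        clinical_dx=("clinical_status", lambda s: (s != "unimpaired").any()),
    )
    agg["comparison"] = ~(agg["apoe_e4"] | agg["psych_dx"]
                          | agg["fair_poor_health"] | agg["clinical_dx"])
    return agg.astype(bool)


def expanded_sample_iisd(
    table: pd.DataFrame,
    settings: PipelineSettings | None = None,
    freeze_standardization: bool = False,
) -> SensitivityReport:
    """Mean IISD in the standardizing vs the expanded sample (impaired
    subjects re-admitted), their correlation across outcomes, and the
    impaired-minus-unimpaired IISD difference per outcome.

    By default the expanded run refits standardization and the mixed
    models from scratch; ``freeze_standardization=True`` scores the
    expanded sample with the standardizing sample's parameters instead.
    """
    settings = replace(settings) if settings else PipelineSettings()
    std_sample = apply_inclusion_rules(table, "standardizing")
    exp_sample = apply_inclusion_rules(table, "expanded")
    if settings.age_center is None:
        settings.age_center = float(std_sample["age_at_visit"].mean())
    std_eval = evaluate_sample(std_sample, settings)
    exp_eval = evaluate_sample(
        exp_sample, settings,
        params=std_eval.params if freeze_standardization else None,
    )
    report = SensitivityReport()
    both = pd.DataFrame({
        "standardizing": std_eval.mean_iisd(),
        "expanded": exp_eval.mean_iisd(),
    })
    report.iisd_by_sample = both
    report.iisd_cross_sample_r = float(
        both["standardizing"].corr(both["expanded"])
    )

    impaired_subjects = set(
        exp_sample.loc[exp_sample["clinical_status"] != "unimpaired",
                       "subject_id"]
    )
    deltas = {}
    for res in exp_eval.iisd:
        mask = res.per_subject.index.isin(impaired_subjects)
        if mask.sum() == 0 or (~mask).sum() == 0:
            deltas[res.outcome] = np.nan
        else:
            deltas[res.outcome] = float(
                res.per_subject[mask].mean() - res.per_subject[~mask].mean()
            )
    report.delta_iisd = pd.Series(deltas, name="delta_iisd")
    if not impaired_subjects:
        report.notes.append("no impaired subjects: contrast is empty")
    return report


def risk_group_iisd(
    table: pd.DataFrame,
    settings: PipelineSettings | None = None,
    min_group_size: int = 10,
) -> SensitivityReport:
    """Per-group, per-outcome mean IISD with cluster-bootstrap CIs, and
    the contrast against the lower-risk comparison group.  Groups with
    fewer than ``min_group_size`` subjects are flagged and their CI
    suppressed."""
    settings = replace(settings) if settings else PipelineSettings()
    exp_sample = apply_inclusion_rules(table, "expanded")
    if settings.age_center is None:
        settings.age_center = float(exp_sample["age_at_visit"].mean())
    exp_eval = evaluate_sample(exp_sample, settings)
    flags = _subject_flags(exp_sample)

    report = SensitivityReport()
    means = {}
    for group in RISK_GROUPS:
        members = set(flags.index[flags[group]])
        col = {}
        cis = {}
        small = len(members) < min_group_size
        for res in exp_eval.iisd:
            sub = res.per_subject[res.per_subject.index.isin(members)]
            col[res.outcome] = float(sub.mean()) if len(sub) else np.nan
            if not small and len(sub) >= 2:
                tmp = summarize_iisd(
                    type(res)(outcome=res.outcome, per_subject=sub,
                              visit_counts=res.visit_counts.loc[sub.index],
                              n_excluded=0),
                    n_boot=settings.n_boot, seed=settings.seed,
                )
                cis[res.outcome] = (tmp.ci_low, tmp.ci_high)
        means[group] = col
        if small:
            report.small_groups.append(group)
            log.warning("risk group %s has < %d subjects; CI suppressed",
                        group, min_group_size)
        else:
            report.group_cis[group] = cis
    report.group_means = pd.DataFrame(means)
    report.group_contrasts = report.group_means.sub(
        report.group_means["comparison"], axis=0
    )
    return report


def validity_sensitivity(
    table: pd.DataFrame,
    settings: PipelineSettings | None = None,
) -> SensitivityReport:
    """Agreement of mean IISD, generalized R^2 and the Ab x age
    interaction between the biomarker sample with and without impaired
    subjects.  Pearson correlation across outcomes (Spearman also
    reported)."""
    settings = replace(settings) if settings else PipelineSettings()
    std_sample = apply_inclusion_rules(table, "standardizing")
    bio_all = apply_inclusion_rules(table, "biomarker")
    impaired_subjects = set(
        bio_all.loc[bio_all["clinical_status"] != "unimpaired", "subject_id"]
    )
    bio_clean = bio_all[~bio_all["subject_id"].isin(impaired_subjects)]
    bio_clean = bio_clean.reset_index(drop=True)
    if settings.age_center is None:
        settings.age_center = float(std_sample["age_at_visit"].mean())
    std_eval = evaluate_sample(std_sample, settings)

    metrics = {}
    for label, sample in (("with_impaired", bio_all),
                          ("without_impaired", bio_clean)):
        val = evaluate_validity(sample, settings, std_eval.params)
        sample_eval = evaluate_sample(sample, settings, params=std_eval.params)
        metrics[label] = pd.DataFrame({
            "mean_iisd": sample_eval.mean_iisd(),
            "r2_glmm": val.table["r2_glmm"],
            "beta_interaction": val.table["beta_interaction"],
        })

    rows = {}
    for metric in ("mean_iisd", "r2_glmm", "beta_interaction"):
        a = metrics["with_impaired"][metric]
        b = metrics["without_impaired"][metric]
        aligned = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
        rows[metric] = {
            "pearson": float(aligned["a"].corr(aligned["b"])),
            "spearman": float(stats.spearmanr(aligned["a"], aligned["b"])[0]),
        }
    report = SensitivityReport()
    report.agreement = pd.DataFrame(rows).T
    report.agreement.index.name = "metric"
    if not impaired_subjects:
        report.notes.append(
            "biomarker sample contains no impaired subjects; the two runs "
            "coincide"
        )
    return report
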