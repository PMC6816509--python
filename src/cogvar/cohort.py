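"""Synthetic longitudinal cohort generation and inclusion rules.

``generate_cohort`` emits a long-format person-visit table (one row per
completed visit, complete score columns) together with a
:class:`TruthRecord` holding the latent ground truth used by
parameter-recovery tests.  ``apply_inclusion_rules`` implements the
three analysis samples:

* ``standardizing`` — subjects with >= 2 complete visits, no baseline
  neurological diagnosis and no MCI-or-worse visit;
* ``biomarker`` — the biomarker-flagged subset, re-admitting impaired
  subjects that the standardizing sample excludes;
* ``expanded`` — the standardizing rules but keeping impaired subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigError, GeneratorConfig

__all__ = [
    "KEY_COLUMNS",
    "RAW_SCORES",
    "SCORE_COLUMNS",
    "TruthRecord",
    "generate_cohort",
    "apply_inclusion_rules",
    "write_cohort_csv",
    "read_cohort_csv",
]

KEY_COLUMNS = ["subject_id", "visit_index"]

#: the twelve raw test scores of the battery, as analysed
RAW_SCORES = [
    "avlt_total", "avlt_delayed", "lm_i", "lm_ii",
    "bvmt_total", "bvmt_delayed", "stroop", "tmt_a", "tmt_b",
    "digsym", "cfl", "mmse",
]

#: all score columns emitted by the generator (raw + AVLT subtotals)
SCORE_COLUMNS = ["avlt_t12", "avlt_t35"] + RAW_SCORES

COVARIATE_COLUMNS = ["sex", "education_band", "literacy", "prior_exposures"]


@dataclass
class TruthRecord:
    """Latent ground truth for one generated cohort."""

    config: GeneratorConfig
    subjects: pd.DataFrame          # one row per subject: latent effects
    test_truth: pd.DataFrame        # per reported score: effective params
    domain_truth: pd.DataFrame      # per domain: fixed-effect parameters

    def to_json(self, path: str) -> None:
        payload = {
            "config": self.config.to_dict(),
            "subjects": self.subjects.to_dict(orient="list"),
            "test_truth": self.test_truth.reset_index().to_dict(orient="list"),
            "domain_truth": self.domain_truth.reset_index().to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def _effective_test_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Effective (loading, error SD, native scale, domain) per reported
    score column, including the derived AVLT total."""
    rows = {}
    for t in config.test_defs:
        rows[t.name] = dict(
            domain=t.domain, loading=t.loading, error_sd=t.error_sd,
            stable_sd=t.stable_sd,
            native_mean=t.native_mean, native_sd=t.native_sd,
            practice_scale=t.practice_scale, higher_better=t.higher_better,
        )
    if _has_avlt_subtotals(config):
        # avlt_total = avlt_t12 + avlt_t35; the shared construct carries
        # a native SD of (ns12 + ns35) while the error and stable terms
        # add in quadrature.
        t12, t35 = config.test("avlt_t12"), config.test("avlt_t35")
        ns = t12.native_sd + t35.native_sd
        err = np.hypot(t12.native_sd * t12.error_sd,
                       t35.native_sd * t35.error_sd) / ns
        stab = np.hypot(t12.native_sd * t12.stable_sd,
                        t35.native_sd * t35.stable_sd) / ns
        rows["avlt_total"] = dict(
            domain=t12.domain, loading=t12.loading, error_sd=float(err),
            stable_sd=float(stab),
            native_mean=t12.native_mean + t35.native_mean, native_sd=ns,
            practice_scale=t12.practice_scale, higher_better=True,
        )
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "score"
    order = [c for c in SCORE_COLUMNS if c in df.index]
    order += [c for c in df.index if c not in order]
    return df.loc[order]


def _has_avlt_subtotals(config: GeneratorConfig) -> bool:
    names = {t.name for t in config.test_defs}
    return {"avlt_t12", "avlt_t35"} <= names


def _practice_bump(exposures: np.ndarray, scale: float, retention: float) -> np.ndarray:
    """Additive practice effect after ``exposures`` prior administrations,
    with geometrically diminishing increments (asymptote scale/(1-r))."""
    if retention == 1.0:
        return scale * exposures
    return scale * (1.0 - retention ** exposures) / (1.0 - retention)


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Simulate a cohort; deterministic given ``config.seed``.

    Each subject draws from its own RNG sub-stream (spawned from the
    config seed), so one subject's realization does not depend on the
    others.  All noise is drawn as standard normals and scaled, so two
    configs differing only in an SD share the same underlying
    realizations ("paired seeds").
    """
    config.validate()
    n = config.n_subjects
    domains = config.domain_defs
    tests = config.test_defs
    dom_index = {d.name: i for i, d in enumerate(domains)}
    imp = config.impairment_model
    amy = config.amyloid_model

    visit_counts = np.array(sorted(config.visit_count_probs), dtype=int)
    visit_probs = np.array([config.visit_count_probs[v] for v in visit_counts])
    exp_counts = np.array(sorted(config.baseline_exposure_probs), dtype=int)
    exp_probs = np.array(
        [config.baseline_exposure_probs[v] for v in exp_counts]
    )

    has_subtotals = _has_avlt_subtotals(config)
    group_labels = sorted({d.group for d in domains if d.group})
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(n)]

    rows: list[dict] = []
    subj_records: list[dict] = []
    for i, rng in enumerate(streams):
        sid = f"S{i + 1:05d}"
        nv = int(visit_counts[rng.choice(len(visit_counts), p=visit_probs)])
        intervals = np.maximum(
            rng.normal(config.interval_mean_years, config.interval_sd_years,
                       size=nv - 1),
            config.interval_min_years,
        )
        age0 = rng.normal(config.baseline_age_mean, config.baseline_age_sd)
        ages = age0 + np.concatenate([[0.0], np.cumsum(intervals)])
        agec = ages - config.reference_age

        male = rng.random() < config.prop_male
        low_edu = rng.random() < config.prop_low_education
        literacy = rng.normal(config.literacy_mean, config.literacy_sd)
        lit_z = (literacy - config.literacy_mean) / config.literacy_sd
        base_exp = int(exp_counts[rng.choice(len(exp_counts), p=exp_probs)])
        apoe4 = rng.random() < config.apoe4_prevalence
        psych = rng.random() < config.psych_dx_prevalence
        poor_health = rng.random() < config.poor_health_prevalence
        neuro_dx = rng.random() < config.baseline_neuro_dx_rate

        in_biomarker = rng.random() < config.biomarker_subsample_frac
        amyloid_latent = (amy.age_loading * (age0 - config.reference_age)
                          + rng.standard_normal())
        abeta = amyloid_latent > amy.threshold
        pet_avail = rng.random() < amy.pet_availability
        csf_avail = rng.random() < amy.csf_availability
        if not (pet_avail or csf_avail):
            pet_avail = True
        # marker noise drawn unconditionally to keep streams aligned
        pib = (amy.pib_base
               + amy.pib_scale * np.exp(amy.pib_shape * amyloid_latent)
               + amy.pib_noise_sd * rng.standard_normal())
        ab42 = (amy.csf_ab42_mean + amy.csf_ab42_slope * amyloid_latent
                + amy.csf_ab42_noise_sd * rng.standard_normal())
        ab4240 = (amy.csf_ratio_mean + amy.csf_ratio_slope * amyloid_latent
                  + amy.csf_ratio_noise_sd * rng.standard_normal())
        ab42 = max(ab42, 150.0)
        ab4240 = max(ab4240, 0.02)

        g = rng.standard_normal()
        group_factor = {grp: rng.standard_normal() for grp in group_labels}
        w = config.shared_intercept_weight
        wg = config.group_weight
        u0 = {}
        for d in domains:
            if d.group:
                shared = w * g + wg * group_factor[d.group]
                unique = np.sqrt(max(1.0 - w * w - wg * wg, 0.0))
            else:
                shared = w * g
                unique = np.sqrt(1.0 - w * w)
            u0[d.name] = d.intercept_sd * (
                shared + unique * rng.standard_normal())
        u1 = {d.name: d.slope_sd * rng.standard_normal() for d in domains}
        stable = {t.name: t.stable_sd * rng.standard_normal() for t in tests}

        impaired = (g + imp.noise_sd * rng.standard_normal()) < imp.threshold
        onset = int(rng.integers(2, nv + 1))  # unimpaired at baseline
        occ_z = rng.standard_normal((nv, len(domains)))
        err_z = rng.standard_normal((nv, len(tests)))

        imp_visit = impaired & (np.arange(1, nv + 1) >= onset)
        mult = np.where(imp_visit, imp.noise_multiplier, 1.0)

        covariate = {
            d.name: (d.sex_effect * male + d.education_effect * low_edu
                     + d.literacy_effect * lit_z)
            for d in domains
        }
        for v in range(nv):
            latent = {}
            for d in domains:
                slope = d.age_slope + (d.abeta_age_interaction if abeta else 0.0)
                val = (covariate[d.name] + slope * agec[v]
                       + u0[d.name] + u1[d.name] * agec[v]
                       + mult[v] * d.occasion_sd * occ_z[v, dom_index[d.name]])
                if imp_visit[v]:
                    years_since = ages[v] - ages[onset - 1]
                    val += imp.level_shift + imp.extra_slope * years_since
                latent[d.name] = val
            exposures = base_exp + v
            row = {
                "subject_id": sid,
                "visit_index": v + 1,
                "age_at_visit": ages[v],
                "sex": "male" if male else "female",
                "education_band": "low" if low_edu else "high",
                "literacy": literacy,
                "prior_exposures": exposures,
                "abeta_status": float(abeta) if in_biomarker else np.nan,
                "pib_dvr": pib if (in_biomarker and pet_avail) else np.nan,
                "csf_ab42": ab42 if (in_biomarker and csf_avail) else np.nan,
                "csf_ab4240": ab4240 if (in_biomarker and csf_avail) else np.nan,
                "clinical_status": ("MCI-or-worse" if imp_visit[v]
                                    else "unimpaired"),
                "baseline_neuro_dx": neuro_dx,
                "apoe_e4": apoe4,
                "psych_dx": psych,
                "fair_poor_health": poor_health,
                "in_biomarker_subsample": in_biomarker,
            }
            for j, t in enumerate(tests):
                construct = (
                    t.loading * latent[t.domain]
                    + stable[t.name]
                    + _practice_bump(np.array(exposures), t.practice_scale,
                                     config.practice_retention)
                    + mult[v] * t.error_sd * err_z[v, j]
                )
                sign = 1.0 if t.higher_better else -1.0
                row[t.name] = t.native_mean + sign * t.native_sd * float(construct)
            if has_subtotals:
                row["avlt_total"] = row["avlt_t12"] + row["avlt_t35"]
            rows.append(row)

        rec = {
            "subject_id": sid, "n_visits": nv, "baseline_age": age0,
            "abeta_status": bool(abeta), "amyloid_latent": amyloid_latent,
            "in_biomarker_subsample": in_biomarker,
            "impaired": bool(impaired), "onset_visit": onset if impaired else 0,
            "g": g,
        }
        for d in domains:
            rec[f"u0_{d.name}"] = u0[d.name]
            rec[f"u1_{d.name}"] = u1[d.name]
        subj_records.append(rec)

    table = pd.DataFrame(rows)
    score_cols = [c for c in SCORE_COLUMNS if c in table.columns]
    score_cols += [t.name for t in tests if t.name not in score_cols]
    ordered = (KEY_COLUMNS + ["age_at_visit", "sex", "education_band",
                              "literacy", "prior_exposures"]
               + score_cols
               + ["abeta_status", "pib_dvr", "csf_ab42", "csf_ab4240",
                  "clinical_status", "baseline_neuro_dx", "apoe_e4",
                  "psych_dx", "fair_poor_health", "in_biomarker_subsample"])
    table = table[ordered]

    domain_truth = pd.DataFrame(
        [{"domain": d.name, "age_slope": d.age_slope,
          "abeta_age_interaction": d.abeta_age_interaction,
          "occasion_sd": d.occasion_sd, "intercept_sd": d.intercept_sd,
          "slope_sd": d.slope_sd} for d in domains]
    ).set_index("domain")
    truth = TruthRecord(
        config=config,
        subjects=pd.DataFrame(subj_records),
        test_truth=_effective_test_truth(config),
        domain_truth=domain_truth,
    )
    return table, truth


# ----------------------------------------------------------------------
def apply_inclusion_rules(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Filter a cohort table to one of the three analysis samples.

    ``standardizing``: drop subjects with < 2 complete visits, a
    baseline neurological diagnosis, or any MCI-or-worse visit.
    ``biomarker``: biomarker-flagged subjects (>= 2 visits, no baseline
    neurological diagnosis), *including* impaired ones.
    ``expanded``: as standardizing but impaired subjects are kept.
    """
    if mode not in ("standardizing", "biomarker", "expanded"):
        raise ValueError(f"unknown inclusion mode: {mode!r}")
    complete = table.dropna(subset=[c for c in SCORE_COLUMNS if c in table])
    counts = complete.groupby("subject_id")["visit_index"].size()
    enough = set(counts.index[counts >= 2])
    keep = complete[complete["subject_id"].isin(enough)]
    keep = keep[~keep["baseline_neuro_dx"].astype(bool)]
    if mode in ("standardizing",):
        impaired_subjects = set(
            keep.loc[keep["clinical_status"] != "unimpaired", "subject_id"]
        )
        keep = keep[~keep["subject_id"].isin(impaired_subjects)]
    if mode == "biomarker":
        keep = keep[keep["in_biomarker_subsample"].astype(bool)]
        keep = keep[keep["abeta_status"].notna()]
    return keep.reset_index(drop=True)


def write_cohort_csv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path: str) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in KEY_COLUMNS + ["age_at_visit"] if c not in table]
    if missing:
        raise ConfigError(f"cohort CSV lacks required columns: {missing}")
    return table
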