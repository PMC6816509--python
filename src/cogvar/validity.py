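"""Criterion-validity metrics.

Four views of how strongly each outcome tracks the criteria of
interest: (1) the fixed age slope with Wald 95% CI; (2) a two-stage
procedure that removes covariate effects with the covariate-only mixed
model and then models the residuals as a function of amyloid status
(Ab) and Ab x age, summarized by the marginal generalized R^2 for
mixed models; (3) the Ab x age interaction coefficient from the full
one-stage mixed model; and (4) Spearman correlations between continuous
amyloid biomarkers and per-subject age-slope estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import (
    AGE_SCALE,
    ModelSpec,
    TrajectoryFit,
    fit_random_slopes,
)

__all__ = [
    "BIOMARKERS",
    "ValidityResult",
    "age_effects",
    "abeta_two_stage",
    "abeta_interaction",
    "biomarker_slope_correlation",
    "abeta_from_markers",
]

log = logging.getLogger(__name__)

#: continuous amyloid markers: name -> True if larger values mean more
#: amyloid (PiB DVR), False if less (CSF measures)
BIOMARKERS = {"pib_dvr": True, "csf_ab42": False, "csf_ab4240": False}


@dataclass
class ValidityResult:
    """Per-outcome criterion metrics (one row per outcome)."""

    table: pd.DataFrame
    details: dict = field(default_factory=dict)

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path)

    def to_json_dict(self) -> dict:
        return self.table.to_dict(orient="index")


def age_effects(fits: dict[str, TrajectoryFit]) -> pd.DataFrame:
    """Age-slope estimates with 95% CIs, one row per converged outcome
    fit (negative = decline)."""
    rows = {}
    for outcome, fit in fits.items():
        if not fit.converged:
            log.warning("age_effects: dropping non-converged fit for %s",
                        outcome)
            continue
        rows[outcome] = fit.params.loc["age_c",
                                       ["estimate", "se", "ci_low", "ci_high"]]
    table = pd.DataFrame(rows).T
    table.index.name = "outcome"
    return table


def _r2_glmm(fit: TrajectoryFit, frame: pd.DataFrame) -> dict[str, float]:
    """Marginal and conditional generalized R^2 from a fitted stage-2
    model.  The random-effect variance uses the random-slopes
    extension: var_re = v0 + 2*c01*mean(age_c) + v1*mean(age_c^2)."""
    # rebuild the fixed-effect prediction variance on the fitted rows
    pred = fit.marginal_residuals  # observed - X beta
    y = frame.loc[pred.index, fit.spec.outcome].to_numpy(dtype=float)
    fixed_pred = y - pred.to_numpy()
    var_f = float(np.var(fixed_pred))
    age_c = (frame.loc[pred.index, "age_at_visit"] - fit.age_center).to_numpy()
    vc = fit.varcomps
    var_re = (vc["var_intercept"]
              + 2.0 * vc["cov_intercept_slope"] * float(np.mean(age_c))
              + vc["var_slope"] * float(np.mean(age_c ** 2)))
    total = var_f + var_re + vc["resid_var"]
    return {
        "r2_marginal": var_f / total,
        "r2_conditional": (var_f + var_re) / total,
        "var_fixed": var_f, "var_random": var_re,
        "var_residual": vc["resid_var"],
    }


def abeta_two_stage(
    residuals: pd.Series,
    frame: pd.DataFrame,
    age_center: float,
) -> dict[str, float]:
    """Stage 2 of the two-stage procedure: mixed model of stage-1
    residuals on Ab + Ab x age with subject random effects, summarized
    by the generalized R^2.

    ``frame`` supplies ``subject_id``, ``age_at_visit`` and
    ``abeta_status`` for the residual rows.
    """
    data = frame.loc[residuals.index,
                     ["subject_id", "age_at_visit", "abeta_status"]].copy()
    data["stage1_resid"] = residuals
    data = data.dropna(subset=["abeta_status", "stage1_resid"])
    if data["abeta_status"].nunique() < 2:
        raise ValueError("degenerate design: abeta_status has a single level")
    data["age_c"] = data["age_at_visit"] - age_center
    data["age_s"] = data["age_c"] / AGE_SCALE  # decades; see trajectory

    import statsmodels.formula.api as smf
    import warnings

    formula = "stage1_resid ~ abeta_status + abeta_status:age_s"
    result = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for re_formula in ("~age_s", "~1"):
            try:
                model = smf.mixedlm(formula, data, groups=data["subject_id"],
                                    re_formula=re_formula)
                result = model.fit(reml=True, method="lbfgs", maxiter=300)
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
                result = None
                continue
            if result is not None:
                break
    if result is None:
        raise RuntimeError("stage-2 mixed model failed to fit")

    fe = result.fe_params
    fixed_pred = result.model.exog @ fe.to_numpy()
    var_f = float(np.var(fixed_pred))
    cov_re = np.asarray(result.cov_re, dtype=float)
    v0 = float(cov_re[0, 0])
    v1 = float(cov_re[1, 1]) if cov_re.shape[0] > 1 else 0.0
    c01 = float(cov_re[0, 1]) if cov_re.shape[0] > 1 else 0.0
    age_s = data["age_s"].to_numpy()
    var_re = v0 + 2.0 * c01 * float(np.mean(age_s)) + v1 * float(np.mean(age_s ** 2))
    total = var_f + var_re + float(result.scale)
    interaction = float(fe.get("abeta_status:age_s", np.nan)) / AGE_SCALE
    return {
        "r2_marginal": var_f / total,
        "r2_conditional": (var_f + var_re) / total,
        "var_fixed": var_f, "var_random": var_re,
        "var_residual": float(result.scale),
        "stage2_interaction": interaction,
    }


def abeta_interaction(
    frame: pd.DataFrame, outcome: str,
    exposures_coding: str = "categorical",
    age_center: float | None = None,
) -> tuple[pd.Series, TrajectoryFit]:
    """One-stage model: full covariate set plus Ab and Ab x age; returns
    the interaction coefficient row (Wald 95% CI) and the fit."""
    spec = ModelSpec(outcome=outcome, include_abeta=True,
                     exposures_coding=exposures_coding, age_center=age_center)
    fit = fit_random_slopes(frame, spec)
    row = fit.params.loc["abeta_status:age_c"].copy()
    row.name = outcome
    return row, fit


def biomarker_slope_correlation(
    slopes: pd.Series,
    biomarkers: pd.DataFrame,
    min_pairs: int = 10,
) -> pd.Series:
    """Spearman rank correlation between per-subject slope estimates and
    each continuous biomarker (pairwise-complete); fewer than
    ``min_pairs`` pairs yields a missing value with a log entry."""
    out = {}
    for marker in (c for c in BIOMARKERS if c in biomarkers.columns):
        merged = pd.concat(
            [slopes.rename("slope"), biomarkers[marker]], axis=1
        ).dropna()
        if len(merged) < min_pairs:
            log.warning("biomarker %s: only %d pairs (< %d); skipping",
                        marker, len(merged), min_pairs)
            out[marker] = np.nan
            continue
        rho, _ = stats.spearmanr(merged["slope"], merged[marker])
        out[marker] = float(rho)
    return pd.Series(out, name=slopes.name)


def abeta_from_markers(
    biomarkers: pd.DataFrame, thresholds: dict[str, float],
) -> pd.Series:
    """Binary amyloid status: 1 if ANY available marker is suprathreshold
    (above threshold for PiB DVR, below for CSF measures), 0 only if all
    available markers are subthreshold, missing if none available."""
    status = pd.Series(np.nan, index=biomarkers.index, dtype=float)
    any_avail = pd.Series(False, index=biomarkers.index)
    any_pos = pd.Series(False, index=biomarkers.index)
    for marker, higher_is_amyloid in BIOMARKERS.items():
        if marker not in biomarkers.columns or marker not in thresholds:
            continue
        vals = biomarkers[marker]
        avail = vals.notna()
        pos = (vals > thresholds[marker]) if higher_is_amyloid \
            else (vals < thresholds[marker])
        any_avail |= avail
        any_pos |= (avail & pos)
    status[any_avail] = any_pos[any_avail].astype(float)
    return status
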