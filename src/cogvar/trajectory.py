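"""Covariate-adjusted random-slopes models per outcome.

Each outcome is modelled with a linear mixed model fit by REML:
fixed effects for age (centred), sex, education band, baseline
literacy and prior battery exposures (optionally amyloid status and its
age interaction), and a per-subject random intercept and random age
slope.  The conditional residual — observed minus fixed-effect
prediction minus the subject's predicted random effects — is the input
to the intraindividual-variability stage, so a subject's own trajectory
is removed and what remains is visit-to-visit inconsistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .cohort import KEY_COLUMNS

__all__ = [
    "ModelSpec",
    "TrajectoryFit",
    "InterceptOnlyFallbackError",
    "prepare_model_frame",
    "fit_random_slopes",
    "subject_slopes",
    "per_subject_ols_slopes",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile

#: age is fitted internally in decades (age_c / 10): with annual random
#: slopes the slope variance is tiny relative to the residual variance
#: and the REML surface is badly scaled; fitting in decades conditions
#: the optimizer, and all reported quantities are rescaled to per-year.
AGE_SCALE = 10.0


class InterceptOnlyFallbackError(RuntimeError):
    """Subject slopes requested from an intercept-only fallback fit."""


@dataclass
class ModelSpec:
    """Specification of one outcome's mixed model."""

    outcome: str
    include_abeta: bool = False
    exposures_coding: str = "categorical"  # "categorical" | "linear"
    random_slopes: bool = True
    residual_type: str = "conditional"     # "conditional" | "marginal"
    age_center: float | None = None        # default: sample mean age

    def fixed_formula(self) -> str:
        expos = ("C(prior_exposures)" if self.exposures_coding == "categorical"
                 else "prior_exposures")
        terms = ["age_s", "C(sex)", "C(education_band)", "literacy", expos]
        if self.include_abeta:
            terms += ["abeta_status", "abeta_status:age_s"]
        return f"Q('{self.outcome}') ~ " + " + ".join(terms)


@dataclass
class TrajectoryFit:
    spec: ModelSpec
    params: pd.DataFrame            # term x (estimate, se, ci_low, ci_high)
    varcomps: dict[str, float]
    residuals: pd.Series            # per person-visit; conditional or
    #                                 marginal per ModelSpec.residual_type
    conditional_residuals: pd.Series
    marginal_residuals: pd.Series
    subject_effects: pd.DataFrame   # subject x (re_intercept, re_slope)
    age_center: float
    converged: bool
    fallback: str | None = None     # None | "intercept_only" | "ols"
    diagnostics: dict = field(default_factory=dict)
    n_obs: int = 0
    n_subjects: int = 0

    @property
    def age_term(self) -> str:
        return "age_c"

    def coefficient(self, term: str) -> pd.Series:
        return self.params.loc[term]

    def to_json_dict(self) -> dict:
        return {
            "outcome": self.spec.outcome,
            "params": self.params.to_dict(orient="index"),
            "varcomps": self.varcomps,
            "age_center": self.age_center,
            "converged": self.converged,
            "fallback": self.fallback,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
        }


def prepare_model_frame(
    scores: pd.DataFrame, cohort: pd.DataFrame, outcome: str
) -> pd.DataFrame:
    """Merge one outcome column with the cohort covariates."""
    covars = ["subject_id", "visit_index", "age_at_visit", "sex",
              "education_band", "literacy", "prior_exposures",
              "abeta_status"]
    covars = [c for c in covars if c in cohort.columns]
    left = scores[KEY_COLUMNS + [outcome]]
    frame = left.merge(cohort[covars], on=KEY_COLUMNS, how="left",
                       validate="one_to_one")
    return frame.dropna(subset=[outcome])


def _wald_table(names, estimates, ses) -> pd.DataFrame:
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    return pd.DataFrame(
        {"estimate": est, "se": se,
         "ci_low": est - Z95 * se, "ci_high": est + Z95 * se},
        index=list(names),
    )


def _fit_mixedlm(formula, data, re_formula):
    model = smf.mixedlm(formula, data, groups=data["subject_id"],
                        re_formula=re_formula)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        last_err = None
        for method in ("lbfgs", "powell"):
            try:
                result = model.fit(reml=True, method=method, maxiter=300)
            except (np.linalg.LinAlgError, ValueError, ZeroDivisionError) as err:
                last_err = err
                continue
            if result.converged:
                return result, None
        try:
            return model.fit(reml=True, maxiter=500), None
        except (np.linalg.LinAlgError, ValueError, ZeroDivisionError) as err:
            return None, last_err or err


def fit_random_slopes(
    frame: pd.DataFrame, spec: ModelSpec
) -> TrajectoryFit:
    """Fit the random-slopes model for one outcome.

    ``frame`` is a model frame from :func:`prepare_model_frame` (or any
    long table with the outcome, covariates, ``subject_id`` and
    ``age_at_visit``).  Wald 95% CIs; REML estimation.  On optimizer
    failure the model is refit with an intercept-only random effect
    (flagged), and as a last resort by ordinary least squares with zero
    variance components (flagged) — the exact solution when data are
    noiseless.
    """
    data = frame.copy()
    if spec.include_abeta and "abeta_status" not in data:
        raise ValueError("include_abeta requires an abeta_status column")
    if spec.include_abeta:
        data = data.dropna(subset=["abeta_status"])
        if data["abeta_status"].nunique() < 2:
            raise ValueError(
                "degenerate design: abeta_status has a single level"
            )
    center = (float(data["age_at_visit"].mean()) if spec.age_center is None
              else spec.age_center)
    data["age_c"] = data["age_at_visit"] - center
    data["age_s"] = data["age_c"] / AGE_SCALE
    formula = spec.fixed_formula()
    n_subjects = data["subject_id"].nunique()

    fallback = None
    result = None
    if spec.random_slopes:
        result, _ = _fit_mixedlm(formula, data, "~age_s")
        if result is None:
            fallback = "intercept_only"
    if result is None and fallback == "intercept_only":
        result, _ = _fit_mixedlm(formula, data, "~1")
    if result is None and not spec.random_slopes:
        result, _ = _fit_mixedlm(formula, data, "~1")

    if result is not None:
        fe = result.fe_params
        est = fe.to_numpy().copy()
        se = result.bse_fe.to_numpy().copy()
        names = []
        for i, name in enumerate(fe.index):
            if "age_s" in name:
                est[i] /= AGE_SCALE
                se[i] /= AGE_SCALE
                names.append(name.replace("age_s", "age_c"))
            else:
                names.append(name)
        params = _wald_table(names, est, se)
        exog = result.model.exog
        marginal = pd.Series(
            result.model.endog - exog @ fe.to_numpy(), index=data.index
        )
        re = result.random_effects
        slope_re = ("age_s" in next(iter(re.values())).index) if re else False
        eff = pd.DataFrame(
            {
                "re_intercept": {g: float(v.iloc[0]) for g, v in re.items()},
                "re_slope": {g: float(v.get("age_s", 0.0)) / AGE_SCALE
                             for g, v in re.items()},
            }
        )
        eff.index.name = "subject_id"
        re_int = data["subject_id"].map(eff["re_intercept"]).to_numpy()
        re_slp = data["subject_id"].map(eff["re_slope"]).to_numpy()
        conditional = marginal - (re_int + re_slp * data["age_c"].to_numpy())
        cov_re = np.asarray(result.cov_re, dtype=float)
        varcomps = {
            "var_intercept": float(cov_re[0, 0]),
            "var_slope": (float(cov_re[1, 1]) / AGE_SCALE ** 2
                          if slope_re else 0.0),
            "cov_intercept_slope": (float(cov_re[0, 1]) / AGE_SCALE
                                    if slope_re else 0.0),
            "resid_var": float(result.scale),
        }
        converged = bool(result.converged)
        diag = {"method": "mixedlm", "reml": True}
    else:
        # last-resort OLS: exact when variance components vanish
        fallback = "ols"
        ols = smf.ols(formula, data).fit()
        est = ols.params.to_numpy().copy()
        se = ols.bse.to_numpy().copy()
        names = []
        for i, name in enumerate(ols.params.index):
            if "age_s" in name:
                est[i] /= AGE_SCALE
                se[i] /= AGE_SCALE
                names.append(name.replace("age_s", "age_c"))
            else:
                names.append(name)
        params = _wald_table(names, est, se)
        marginal = pd.Series(ols.resid.to_numpy(), index=data.index)
        conditional = marginal.copy()
        eff = pd.DataFrame(
            {"re_intercept": 0.0, "re_slope": 0.0},
            index=pd.Index(sorted(data["subject_id"].unique()),
                           name="subject_id"),
        )
        varcomps = {"var_intercept": 0.0, "var_slope": 0.0,
                    "cov_intercept_slope": 0.0,
                    "resid_var": float(np.var(marginal, ddof=1))}
        converged = True
        diag = {"method": "ols_fallback"}

    residuals = conditional if spec.residual_type == "conditional" else marginal
    keys = [c for c in KEY_COLUMNS if c in data.columns]
    residuals = residuals.copy()
    residuals.index = data.index
    fit = TrajectoryFit(
        spec=spec, params=params, varcomps=varcomps,
        residuals=residuals,
        conditional_residuals=pd.Series(conditional, index=data.index),
        marginal_residuals=pd.Series(marginal, index=data.index),
        subject_effects=eff, age_center=center, converged=converged,
        fallback=fallback, diagnostics=diag,
        n_obs=len(data), n_subjects=n_subjects,
    )
    fit.diagnostics["subject_ids"] = data["subject_id"].to_numpy()
    if all(c in data.columns for c in KEY_COLUMNS):
        fit.diagnostics["keys"] = data[KEY_COLUMNS].reset_index(drop=True)
    return fit


def subject_slopes(fit: TrajectoryFit) -> pd.Series:
    """Per-subject age-slope estimates: fixed age effect plus the
    subject's predicted random slope."""
    if fit.fallback == "intercept_only":
        raise InterceptOnlyFallbackError(
            "fit fell back to intercept-only random effects "
            "(see TrajectoryFit.fallback); subject slopes are undefined"
        )
    beta_age = float(fit.params.loc["age_c", "estimate"])
    slopes = beta_age + fit.subject_effects["re_slope"]
    slopes.name = f"slope_{fit.spec.outcome}"
    return slopes


def per_subject_ols_slopes(frame: pd.DataFrame, outcome: str) -> pd.Series:
    """Unshrunken alternative to BLUP-based slopes: an ordinary
    least-squares age slope per subject (subjects with < 2 visits are
    missing; 2 visits give the two-point slope)."""

    def _slope(g: pd.DataFrame) -> float:
        if len(g) < 2:
            return np.nan
        x = g["age_at_visit"].to_numpy(dtype=float)
        y = g[outcome].to_numpy(dtype=float)
        xc = x - x.mean()
        return float((xc * (y - y.mean())).sum() / (xc ** 2).sum())

    slopes = frame.groupby("subject_id").apply(_slope,
                                               include_groups=False)
    slopes.name = f"slope_{outcome}"
    return slopes
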