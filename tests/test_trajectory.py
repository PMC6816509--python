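"""Random-slopes trajectory models: recovery, residuals, invariances."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from cogvar import generate_cohort
from cogvar.composites import standardize
from cogvar.config import ImpairmentModel
from cogvar.trajectory import (
    InterceptOnlyFallbackError,
    ModelSpec,
    fit_random_slopes,
    per_subject_ols_slopes,
    prepare_model_frame,
    subject_slopes,
)
from conftest import one_domain_config


def _fit_one_domain(cfg, outcome="t1", **spec_kw):
    table, truth = generate_cohort(cfg)
    z, params = standardize(
        table, score_columns=[t.name for t in cfg.test_defs])
    frame = prepare_model_frame(z, table, outcome)
    fit = fit_random_slopes(frame, ModelSpec(outcome, **spec_kw))
    return table, truth, params, fit


class TestNoiselessLimit:
    @pytest.fixture(scope="class")
    def noiseless(self):
        cfg = one_domain_config(n_subjects=30, seed=5)
        d = cfg.domain_defs[0]
        d.intercept_sd = d.slope_sd = d.occasion_sd = 0.0
        for t in cfg.test_defs:
            t.error_sd = 0.0
        cfg.impairment_model = ImpairmentModel(
            level_shift=0.0, extra_slope=0.0, noise_multiplier=1.0)
        return _fit_one_domain(cfg)

    def test_residuals_vanish(self, noiseless):
        *_, fit = noiseless
        assert np.max(np.abs(fit.residuals)) < 1e-8

    def test_age_slope_exact(self, noiseless):
        _, truth, params, fit = noiseless
        t1 = truth.test_truth.loc["t1"]
        expected = (t1.loading * truth.domain_truth.loc["dom", "age_slope"]
                    * t1.native_sd / params.sds["t1"])
        assert fit.params.loc["age_c", "estimate"] == pytest.approx(
            expected, abs=1e-6)


class TestRecovery:
    @pytest.fixture(scope="class")
    def moderate(self):
        cfg = one_domain_config(n_subjects=600, seed=21, error_sd=0.25,
                                visit_count_probs={4: 1.0})
        cfg.domain_defs[0].slope_sd = 0.05
        return _fit_one_domain(cfg)

    def test_age_slope_within_sampling_error(self, moderate):
        _, truth, params, fit = moderate
        t1 = truth.test_truth.loc["t1"]
        expected = (t1.loading * truth.domain_truth.loc["dom", "age_slope"]
                    * t1.native_sd / params.sds["t1"])
        row = fit.params.loc["age_c"]
        assert abs(row.estimate - expected) < 3 * row.se

    def test_wald_ci_symmetric(self, moderate):
        *_, fit = moderate
        lo = fit.params["estimate"] - fit.params["ci_low"]
        hi = fit.params["ci_high"] - fit.params["estimate"]
        np.testing.assert_allclose(lo, hi, atol=1e-12)

    def test_subject_slope_rank_recovery(self, moderate):
        _, truth, params, fit = moderate
        est = subject_slopes(fit)
        true_slopes = truth.subjects.set_index("subject_id")["u1_dom"]
        merged = pd.concat([est, true_slopes], axis=1).dropna()
        rho = scipy.stats.spearmanr(merged.iloc[:, 0], merged.iloc[:, 1])[0]
        assert rho >= 0.6

    def test_slope_count_matches_subjects(self, moderate):
        *_, fit = moderate
        assert len(subject_slopes(fit)) == fit.n_subjects

    def test_per_subject_ols_slopes_track_blups(self, moderate):
        table, truth, params, fit = moderate
        z, _ = standardize(
            table, score_columns=["t1", "t2", "t3"])
        frame = prepare_model_frame(z, table, "t1")
        ols = per_subject_ols_slopes(frame, "t1")
        blup = subject_slopes(fit)
        merged = pd.concat([ols, blup], axis=1, keys=["ols", "blup"]).dropna()
        # unshrunken per-subject slopes agree in ordering with BLUPs
        rho = scipy.stats.spearmanr(merged["ols"], merged["blup"])[0]
        assert rho > 0.7
        # two-point oracle on one subject
        g = frame[frame["subject_id"] == frame["subject_id"].iloc[0]]
        manual = np.polyfit(g["age_at_visit"], g["t1"], 1)[0]
        assert ols[g["subject_id"].iloc[0]] == pytest.approx(manual,
                                                             abs=1e-10)

    def test_variance_components_reconstruct_outcome_variance(self, moderate):
        # marginal-residual variance should match the model-implied
        # random-effect + residual variance within 10%
        table, _, params, fit = moderate
        resid = fit.marginal_residuals.to_numpy()
        vc = fit.varcomps
        agec = (table["age_at_visit"] - fit.age_center).to_numpy()
        model_var = (vc["var_intercept"] + vc["resid_var"]
                     + vc["var_slope"] * float(np.mean(agec ** 2))
                     + 2 * vc["cov_intercept_slope"] * float(np.mean(agec)))
        assert model_var == pytest.approx(float(np.var(resid, ddof=1)),
                                          rel=0.10)


class TestResidualProperties:
    def test_shift_invariance(self, scored, std_sample):
        scores, _ = scored
        frame = prepare_model_frame(scores, std_sample, "avlt_total")
        fit1 = fit_random_slopes(frame, ModelSpec("avlt_total"))
        shifted = frame.assign(avlt_total=frame["avlt_total"] + 5.0)
        fit2 = fit_random_slopes(shifted, ModelSpec("avlt_total"))
        np.testing.assert_allclose(fit1.residuals, fit2.residuals, atol=1e-6)

    def test_within_subject_residual_mean_small(self, small_eval):
        ev, _ = small_eval
        fit = ev.fits["avlt_total"]
        sids = fit.diagnostics["subject_ids"]
        means = pd.Series(fit.conditional_residuals.to_numpy()).groupby(
            pd.Series(sids)).agg(["mean", "size"])
        at_least3 = means[means["size"] >= 3]["mean"]
        assert at_least3.abs().median() < 0.05

    def test_conditional_vs_marginal_residuals(self, small_eval):
        ev, _ = small_eval
        fit = ev.fits["avlt_total"]
        # conditional residuals remove subject trajectories, so they are
        # strictly less variable than marginal residuals
        assert (fit.conditional_residuals.std()
                < 0.8 * fit.marginal_residuals.std())

    def test_intercept_only_fallback_blocks_subject_slopes(self, small_eval):
        ev, _ = small_eval
        fit = ev.fits["avlt_total"]
        import copy

        broken = copy.copy(fit)
        broken.fallback = "intercept_only"
        with pytest.raises(InterceptOnlyFallbackError, match="fallback"):
            subject_slopes(broken)

    def test_ols_oracle_when_variances_constrained_to_zero(
            self, monkeypatch):
        # with the random-effect variances pinned at zero (the OLS
        # fallback path), fixed effects must equal an ordinary
        # least-squares fit on the same design
        import statsmodels.formula.api as smf
        import cogvar.trajectory as tj

        rng = np.random.default_rng(13)
        rows = []
        for i, sid in enumerate(["a", "b", "c", "d"]):
            for v in range(2):
                rows.append({
                    "subject_id": sid, "visit_index": v + 1,
                    "age_at_visit": 58.0 + 3 * i + 2.5 * v,
                    "sex": "male" if i % 2 else "female",
                    "education_band": "low" if i < 2 else "high",
                    "literacy": 100.0 + i, "prior_exposures": v + 1,
                    "y": rng.normal(),
                })
        frame = pd.DataFrame(rows)
        monkeypatch.setattr(tj, "_fit_mixedlm",
                            lambda *a, **k: (None, RuntimeError("forced")))
        fit = fit_random_slopes(frame, ModelSpec("y"))
        assert fit.fallback == "ols"
        data = frame.assign(
            age_s=(frame["age_at_visit"] - fit.age_center) / 10.0)
        ols = smf.ols("y ~ age_s + C(sex) + C(education_band) + literacy"
                      " + C(prior_exposures)", data).fit()
        assert fit.params.loc["age_c", "estimate"] == pytest.approx(
            ols.params["age_s"] / 10.0, abs=1e-10)
        np.testing.assert_allclose(fit.residuals, ols.resid, atol=1e-10)

    def test_abeta_requires_column(self, scored, std_sample):
        scores, _ = scored
        frame = prepare_model_frame(scores, std_sample, "avlt_total")
        frame = frame.drop(columns=["abeta_status"], errors="ignore")
        with pytest.raises(ValueError, match="abeta_status"):
            fit_random_slopes(frame, ModelSpec("avlt_total",
                                               include_abeta=True))
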