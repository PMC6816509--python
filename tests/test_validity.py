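"""Criterion-validity metrics: age effects, amyloid models, biomarker
correlations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cogvar import default_config, generate_cohort
from cogvar.cohort import apply_inclusion_rules
from cogvar.composites import table2_registry
from cogvar.pipeline import PipelineSettings, evaluate_validity, score_sample
from cogvar.trajectory import ModelSpec, fit_random_slopes, prepare_model_frame
from cogvar.validity import (
    abeta_from_markers,
    abeta_two_stage,
    age_effects,
    biomarker_slope_correlation,
)


@pytest.fixture(scope="module")
def bio_validity(small_cohort):
    table, truth = small_cohort
    std = apply_inclusion_rules(table, "standardizing")
    bio = apply_inclusion_rules(table, "biomarker")
    settings = PipelineSettings(outcomes=["avlt_total", "stroop"],
                                n_boot=200, seed=2,
                                age_center=float(std["age_at_visit"].mean()))
    _, params = score_sample(std, table2_registry())
    return evaluate_validity(bio, settings, params), bio, params


class TestAgeEffects:
    def test_table_from_fits(self, small_eval):
        ev, _ = small_eval
        table = age_effects(ev.fits)
        assert set(table.index) == set(ev.fits)
        assert (table["ci_low"] <= table["estimate"]).all()
        assert (table["estimate"] <= table["ci_high"]).all()

    def test_all_outcomes_decline(self, small_eval):
        ev, _ = small_eval
        table = age_effects(ev.fits)
        assert (table["estimate"] < 0).all()

    def test_executive_declines_faster_than_memory(self, small_eval):
        # generated executive slope is twice the memory slope
        ev, _ = small_eval
        table = age_effects(ev.fits)
        assert table.loc["stroop", "estimate"] < \
            table.loc["avlt_total", "estimate"]

    def test_nonconverged_fits_dropped(self, small_eval, caplog):
        import copy
        import logging

        ev, _ = small_eval
        fits = {k: v for k, v in ev.fits.items()}
        broken = copy.copy(fits["stroop"])
        broken.converged = False
        fits["stroop"] = broken
        with caplog.at_level(logging.WARNING, logger="cogvar.validity"):
            table = age_effects(fits)
        assert "stroop" not in table.index
        assert "non-converged" in caplog.text


class TestTwoStage:
    def test_r2_reconstructs_from_variance_components(self, bio_validity):
        val, *_ = bio_validity
        for outcome, det in val.details.items():
            r2 = det["r2"]
            total = r2["var_fixed"] + r2["var_random"] + r2["var_residual"]
            assert r2["r2_marginal"] == pytest.approx(
                r2["var_fixed"] / total, abs=1e-8)
            assert r2["r2_conditional"] == pytest.approx(
                (r2["var_fixed"] + r2["var_random"]) / total, abs=1e-8)

    def test_r2_in_unit_interval(self, bio_validity):
        val, *_ = bio_validity
        assert ((val.table["r2_glmm"] >= 0)
                & (val.table["r2_glmm"] <= 1)).all()

    def test_single_group_degenerate(self, bio_validity, small_cohort):
        _, bio, params = bio_validity
        forced = bio.copy()
        forced["abeta_status"] = 1.0
        scores, _ = score_sample(forced, table2_registry(), params=params)
        frame = prepare_model_frame(scores, forced, "avlt_total")
        fit = fit_random_slopes(frame, ModelSpec("avlt_total"))
        with pytest.raises(ValueError, match="degenerate"):
            abeta_two_stage(fit.residuals, frame, fit.age_center)


class TestInteraction:
    def test_ci_symmetric_and_contains_estimate(self, bio_validity):
        val, *_ = bio_validity
        t = val.table
        np.testing.assert_allclose(
            t["beta_interaction"] - t["interaction_ci_low"],
            t["interaction_ci_high"] - t["beta_interaction"], atol=1e-10)
        assert (t["interaction_ci_low"] <= t["beta_interaction"]).all()

    def test_null_interaction_centered_on_zero(self):
        # no amyloid effect on trajectories at all: estimates scatter
        # around zero
        ests = []
        for seed in range(6):
            cfg = default_config(seed=50 + seed, n_subjects=300,
                                 biomarker_subsample_frac=0.8)
            for d in cfg.domain_defs:
                d.abeta_age_interaction = 0.0
            table, _ = generate_cohort(cfg)
            bio = apply_inclusion_rules(table, "biomarker")
            scores, params = score_sample(bio, table2_registry())
            frame = prepare_model_frame(scores, bio, "avlt_total")
            fit = fit_random_slopes(frame, ModelSpec("avlt_total",
                                                     include_abeta=True))
            ests.append(fit.params.loc["abeta_status:age_c", "estimate"])
        # bound ~2.7 standard errors of the 6-replicate mean
        assert abs(np.mean(ests)) < 0.012


class TestBiomarkerCorrelation:
    def test_expected_sign_conventions(self):
        # worse decline accompanies higher PiB burden and lower CSF
        # amyloid values.  An executive outcome is used because its low
        # residual error gives the least-attenuated slope estimates (the
        # same reason executive measures show the clearest biomarker
        # signal in practice); the biomarker sample must be large enough
        # (~170 subjects) for the sign to be stable.
        from cogvar.trajectory import subject_slopes

        table, _ = generate_cohort(default_config(seed=60, n_subjects=800))
        bio = apply_inclusion_rules(table, "biomarker")
        scores, params = score_sample(bio, table2_registry())
        frame = prepare_model_frame(scores, bio, "stroop")
        fit = fit_random_slopes(frame, ModelSpec("stroop"))
        markers = bio.groupby("subject_id")[
            ["pib_dvr", "csf_ab42", "csf_ab4240"]].first()
        rho = biomarker_slope_correlation(subject_slopes(fit), markers)
        assert rho["pib_dvr"] < 0
        assert rho["csf_ab42"] > 0
        assert rho["csf_ab4240"] > 0

    def test_too_few_pairs_gives_missing(self, caplog):
        import logging

        slopes = pd.Series([0.1, 0.2, 0.3], index=["a", "b", "c"])
        markers = pd.DataFrame({"pib_dvr": [1.1, 1.2, np.nan]},
                               index=["a", "b", "c"])
        with caplog.at_level(logging.WARNING, logger="cogvar.validity"):
            rho = biomarker_slope_correlation(slopes, markers)
        assert np.isnan(rho["pib_dvr"])
        assert "skipping" in caplog.text

    def test_tied_values_match_midrank_oracle(self):
        slopes = pd.Series([0.1, 0.5, 0.3, 0.2, 0.4],
                           index=list("abcde"))
        markers = pd.DataFrame(
            {"pib_dvr": [1.2, 1.2, 1.2, 1.5, 1.1]}, index=list("abcde"))
        rho = biomarker_slope_correlation(slopes, markers, min_pairs=5)

        def midranks(x):
            order = np.argsort(x, kind="mergesort")
            ranks = np.empty(len(x), dtype=float)
            sx = np.asarray(x)[order]
            i = 0
            while i < len(x):
                j = i
                while j + 1 < len(x) and sx[j + 1] == sx[i]:
                    j += 1
                ranks[order[i:j + 1]] = (i + j) / 2 + 1
                i = j + 1
            return ranks

        r1 = midranks(slopes.to_numpy())
        r2 = midranks(markers["pib_dvr"].to_numpy())
        oracle = np.corrcoef(r1, r2)[0, 1]
        assert rho["pib_dvr"] == pytest.approx(oracle, abs=1e-12)

    def test_slope_recovery_against_true_biomarker(self):
        # a biomarker equal to the true subject slope should correlate
        # strongly with the estimated slopes
        from cogvar.trajectory import subject_slopes
        from conftest import one_domain_config

        cfg = one_domain_config(n_subjects=300, seed=31, error_sd=0.25,
                                visit_count_probs={4: 1.0})
        cfg.domain_defs[0].slope_sd = 0.05
        table, truth = generate_cohort(cfg)
        from cogvar.composites import standardize

        z, _ = standardize(table, score_columns=["t1", "t2", "t3"])
        frame = prepare_model_frame(z, table, "t1")
        fit = fit_random_slopes(frame, ModelSpec("t1"))
        est = subject_slopes(fit)
        true = truth.subjects.set_index("subject_id")["u1_dom"]
        markers = pd.DataFrame({"pib_dvr": true})
        rho = biomarker_slope_correlation(est, markers)
        assert abs(rho["pib_dvr"]) >= 0.6


class TestAbetaFromMarkers:
    def test_any_suprathreshold_rule(self):
        markers = pd.DataFrame({
            "pib_dvr": [1.5, 1.0, np.nan, np.nan],
            "csf_ab42": [900.0, 900.0, 500.0, np.nan],
        }, index=list("wxyz"))
        thresholds = {"pib_dvr": 1.19, "csf_ab42": 700.0}
        status = abeta_from_markers(markers, thresholds)
        assert status["w"] == 1.0   # PiB positive despite benign CSF
        assert status["x"] == 0.0   # all available markers subthreshold
        assert status["y"] == 1.0   # CSF positive, PiB unavailable
        assert np.isnan(status["z"])
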