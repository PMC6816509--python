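"""Shared fixtures: small cohorts and fitted pipelines, session-scoped
so the expensive mixed-model fits run once."""

from __future__ import annotations

import pandas as pd
import pytest

from cogvar import default_config, generate_cohort
from cogvar.cohort import apply_inclusion_rules
from cogvar.composites import table2_registry
from cogvar.config import DomainDef, GeneratorConfig, TestDef
from cogvar.pipeline import PipelineSettings, evaluate_sample, score_sample


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at reduced size (n=250, seed 11)."""
    table, truth = generate_cohort(default_config(seed=11, n_subjects=250))
    return table, truth


@pytest.fixture(scope="session")
def std_sample(small_cohort):
    table, _ = small_cohort
    return apply_inclusion_rules(table, "standardizing")


@pytest.fixture(scope="session")
def scored(std_sample):
    return score_sample(std_sample, table2_registry())


@pytest.fixture(scope="session")
def small_eval(std_sample):
    """Fitted pipeline on a handful of outcomes (shared across tests)."""
    settings = PipelineSettings(
        outcomes=["avlt_total", "lm_ii", "stroop", "mmse",
                  "PACC3", "THEO-EXEC-FN"],
        n_boot=300, seed=5,
    )
    return evaluate_sample(std_sample, settings), settings


def one_domain_config(
    n_subjects: int = 150, n_tests: int = 3, error_sd: float = 0.4,
    seed: int = 0, **overrides,
) -> GeneratorConfig:
    """One latent domain, equal-error tests, small occasion noise: the
    setting where averaging k tests should shrink error by ~1/sqrt(k)."""
    dom = DomainDef("dom", age_slope=-0.03, abeta_age_interaction=0.0,
                    sex_effect=-0.2, education_effect=-0.2,
                    literacy_effect=0.2, intercept_sd=0.85, slope_sd=0.025,
                    occasion_sd=0.05)
    tests = [TestDef(f"t{i}", "dom", 0.85, error_sd, 0.05, 50.0, 10.0)
             for i in range(1, n_tests + 1)]
    cfg = GeneratorConfig(n_subjects=n_subjects, domain_defs=[dom],
                          test_defs=tests, biomarker_subsample_frac=0.0,
                          seed=seed, **overrides)
    cfg.validate()
    return cfg


def toy_visits(rows: list[tuple]) -> pd.DataFrame:
    """Hand-built long table: rows of (subject, visit, x, y)."""
    return pd.DataFrame(rows, columns=["subject_id", "visit_index", "x", "y"])
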