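"""Configuration for the synthetic longitudinal cognitive cohort.

The generator emulates a middle-aged, amyloid-enriched ageing cohort
followed with a multi-test neuropsychological battery: 2-5 visits per
subject roughly 2.5 years apart, three correlated latent cognitive
domains (immediate memory, delayed memory, executive function) plus a
weakly loaded "global" construct for screening-type tests, test-specific
measurement error, practice effects with diminishing increments, and
amyloid-beta (Ab) accelerated age-related decline in a biomarker
subsample.

All latent-trajectory quantities are expressed in latent-SD units; test
scores are mapped onto plausible native scales via per-test mean/SD and
a direction flag (timed tests score "lower is better").
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = [
    "ConfigError",
    "DomainDef",
    "TestDef",
    "ImpairmentModel",
    "AmyloidModel",
    "GeneratorConfig",
    "default_config",
]


class ConfigError(ValueError):
    """Raised when a generator configuration is internally inconsistent."""


@dataclass
class DomainDef:
    """A latent cognitive domain and its trajectory model.

    ``age_slope`` is the fixed-effect annual change (latent SD/year) for
    amyloid-negative subjects; ``abeta_age_interaction`` is the extra
    annual change for amyloid-positive subjects.  Covariate effects are
    additive offsets on the latent scale.  ``occasion_sd`` is visit-level
    noise shared by every test loading on the domain.
    """

    name: str
    age_slope: float
    abeta_age_interaction: float
    sex_effect: float          # male minus female, latent SD
    education_effect: float    # low band minus high band, latent SD
    literacy_effect: float     # per SD of baseline literacy
    intercept_sd: float
    slope_sd: float            # SD of subject random age slopes (SD/yr)
    occasion_sd: float
    group: str = ""            # domains sharing a non-empty group label
    #                            share an extra intercept factor


@dataclass
class TestDef:
    """One administered test (or subscore) of the battery."""

    name: str
    domain: str
    loading: float             # in (0, 1]
    error_sd: float            # test-specific error, latent-SD units
    practice_scale: float      # size of the first practice bump (SD)
    native_mean: float
    native_sd: float
    higher_better: bool = True
    stable_sd: float = 0.0     # stable test-specific subject effect
    #                            ("methods effect": raises reliability,
    #                            lowers cross-test correlations)


@dataclass
class ImpairmentModel:
    """Links low latent cognition to an MCI-or-worse clinical flag.

    A subject is impaired when ``g + N(0, noise_sd**2) < threshold``
    where ``g`` is the shared cognitive factor; onset is a uniformly
    drawn visit >= 2 (everyone is unimpaired at baseline).  From onset
    the subject's latent level drops by ``level_shift``, declines by an
    extra ``extra_slope`` per year, and occasion noise and test errors
    are inflated by ``noise_multiplier``.
    """

    threshold: float = -1.84
    noise_sd: float = 0.5
    level_shift: float = -0.4
    extra_slope: float = -0.02
    noise_multiplier: float = 1.6


@dataclass
class AmyloidModel:
    """Latent amyloid variable, binary status and continuous markers.

    Latent amyloid ``A = age_loading * (baseline_age - reference_age) +
    N(0, 1)``; binary positivity is ``A > threshold``.  Continuous
    markers are monotone transforms of ``A`` plus noise: PiB DVR
    increases with ``A``, CSF Ab42 and the Ab42/40 ratio decrease.
    """

    age_loading: float = 0.05
    threshold: float = 0.585
    pet_availability: float = 0.91
    csf_availability: float = 0.57
    pib_base: float = 1.0
    pib_scale: float = 0.35
    pib_shape: float = 0.55
    pib_noise_sd: float = 0.05
    csf_ab42_mean: float = 800.0
    csf_ab42_slope: float = -180.0
    csf_ab42_noise_sd: float = 80.0
    csf_ratio_mean: float = 0.10
    csf_ratio_slope: float = -0.025
    csf_ratio_noise_sd: float = 0.008


@dataclass
class GeneratorConfig:
    n_subjects: int = 1063
    visit_count_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.25, 3: 0.35, 4: 0.25, 5: 0.15}
    )
    interval_mean_years: float = 2.51
    interval_sd_years: float = 0.40
    interval_min_years: float = 1.0
    baseline_age_mean: float = 58.2
    baseline_age_sd: float = 6.4
    reference_age: float = 60.0
    prop_male: float = 0.30
    prop_low_education: float = 0.38
    literacy_mean: float = 107.0
    literacy_sd: float = 9.0
    # probability that a subject enters with 1 vs 2 earlier battery
    # administrations (some tests join the battery after study entry)
    baseline_exposure_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.5, 2: 0.5}
    )
    practice_retention: float = 0.5  # diminishing-increment ratio
    shared_intercept_weight: float = 0.55  # general-factor share of u0
    group_weight: float = 0.55  # extra shared factor within domain groups
    domain_defs: list[DomainDef] = field(default_factory=list)
    test_defs: list[TestDef] = field(default_factory=list)
    abeta_prevalence: float = 0.26   # target fraction in the subsample
    biomarker_subsample_frac: float = 0.213
    amyloid_model: AmyloidModel = field(default_factory=AmyloidModel)
    impairment_model: ImpairmentModel = field(default_factory=ImpairmentModel)
    baseline_neuro_dx_rate: float = 0.04
    apoe4_prevalence: float = 0.38
    psych_dx_prevalence: float = 0.20
    poor_health_prevalence: float = 0.12
    seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        for name, probs in (
            ("visit_count_probs", self.visit_count_probs),
            ("baseline_exposure_probs", self.baseline_exposure_probs),
        ):
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-8:
                raise ConfigError(f"{name} must sum to 1 (got {total})")
            if any(p < 0 for p in probs.values()):
                raise ConfigError(f"{name} has negative entries")
        if any(v not in (2, 3, 4, 5) for v in self.visit_count_probs):
            raise ConfigError("visit counts must lie in {2, 3, 4, 5}")
        for frac_name in (
            "prop_male",
            "prop_low_education",
            "abeta_prevalence",
            "biomarker_subsample_frac",
            "baseline_neuro_dx_rate",
            "apoe4_prevalence",
            "psych_dx_prevalence",
            "poor_health_prevalence",
        ):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{frac_name} must be in [0, 1] (got {v})")
        sd_fields = [
            ("interval_sd_years", self.interval_sd_years),
            ("baseline_age_sd", self.baseline_age_sd),
            ("literacy_sd", self.literacy_sd),
        ]
        for d in self.domain_defs:
            sd_fields += [
                (f"{d.name}.intercept_sd", d.intercept_sd),
                (f"{d.name}.slope_sd", d.slope_sd),
                (f"{d.name}.occasion_sd", d.occasion_sd),
            ]
        for t in self.test_defs:
            sd_fields.append((f"{t.name}.error_sd", t.error_sd))
        for name, v in sd_fields:
            if v < 0:
                raise ConfigError(f"SD {name} must be >= 0 (got {v})")
        if not self.domain_defs or not self.test_defs:
            raise ConfigError("domain_defs and test_defs must be non-empty")
        domains = {d.name for d in self.domain_defs}
        if len(domains) != len(self.domain_defs):
            raise ConfigError("duplicate domain names")
        seen = set()
        for t in self.test_defs:
            if t.domain not in domains:
                raise ConfigError(f"test {t.name} maps to unknown domain {t.domain}")
            if t.name in seen:
                raise ConfigError(f"duplicate test name {t.name}")
            seen.add(t.name)
            if not 0.0 < t.loading <= 1.0:
                raise ConfigError(f"loading for {t.name} must be in (0, 1]")
            if t.native_sd <= 0:
                raise ConfigError(f"native_sd for {t.name} must be > 0")
        if not 0.0 <= self.shared_intercept_weight <= 1.0:
            raise ConfigError("shared_intercept_weight must be in [0, 1]")
        if not 0.0 <= self.group_weight <= 1.0:
            raise ConfigError("group_weight must be in [0, 1]")
        if any(d.group for d in self.domain_defs):
            if self.shared_intercept_weight ** 2 + self.group_weight ** 2 > 1.0:
                raise ConfigError(
                    "shared_intercept_weight^2 + group_weight^2 must be <= 1"
                )
        for t in self.test_defs:
            if t.stable_sd < 0:
                raise ConfigError(f"stable_sd for {t.name} must be >= 0")

    # ------------------------------------------------------------------
    def domain(self, name: str) -> DomainDef:
        for d in self.domain_defs:
            if d.name == name:
                return d
        raise KeyError(name)

    def test(self, name: str) -> TestDef:
        for t in self.test_defs:
            if t.name == name:
                return t
        raise KeyError(name)

    # -- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "GeneratorConfig":
        data = dict(data)
        data["domain_defs"] = [DomainDef(**d) for d in data.get("domain_defs", [])]
        data["test_defs"] = [TestDef(**t) for t in data.get("test_defs", [])]
        if isinstance(data.get("amyloid_model"), dict):
            data["amyloid_model"] = AmyloidModel(**data["amyloid_model"])
        if isinstance(data.get("impairment_model"), dict):
            data["impairment_model"] = ImpairmentModel(**data["impairment_model"])
        for key in ("visit_count_probs", "baseline_exposure_probs"):
            if key in data:
                data[key] = {int(k): float(v) for k, v in data[key].items()}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_file(cls, path: str) -> "GeneratorConfig":
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} did not parse to a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _default_domains() -> list[DomainDef]:
    common = dict(intercept_sd=0.85, slope_sd=0.025)
    return [
        DomainDef("imm_memory", age_slope=-0.020, abeta_age_interaction=-0.040,
                  sex_effect=-0.30, education_effect=-0.25, literacy_effect=0.25,
                  occasion_sd=0.15, group="memory", **common),
        DomainDef("del_memory", age_slope=-0.020, abeta_age_interaction=-0.040,
                  sex_effect=-0.30, education_effect=-0.25, literacy_effect=0.25,
                  occasion_sd=0.15, group="memory", **common),
        DomainDef("executive", age_slope=-0.040, abeta_age_interaction=-0.040,
                  sex_effect=0.0, education_effect=-0.25, literacy_effect=0.20,
                  occasion_sd=0.10, **common),
        DomainDef("global", age_slope=-0.015, abeta_age_interaction=-0.020,
                  sex_effect=-0.10, education_effect=-0.30, literacy_effect=0.30,
                  intercept_sd=0.85, slope_sd=0.020, occasion_sd=0.12),
    ]


def _default_tests() -> list[TestDef]:
    # AVLT is generated as trial subtotals (trials 1-2 and 3-5) so both
    # the trial-split empirical composites and the standard total are
    # available; the total is the sum of the subtotals.  Error SDs are
    # deliberately distinct and well spread across tests (executive
    # tests lowest, MMSE highest) so that relative test consistency has
    # a well-defined ground truth; the common stable_sd adds a methods
    # effect without disturbing that ordering.
    kw = dict(stable_sd=0.40)
    return [
        TestDef("avlt_t12", "imm_memory", 0.85, 0.537, 0.06, 13.0, 4.0, **kw),
        TestDef("avlt_t35", "imm_memory", 0.85, 0.537, 0.06, 37.0, 8.0, **kw),
        TestDef("avlt_delayed", "del_memory", 0.85, 0.52, 0.06, 10.5, 2.8,
                **kw),
        TestDef("lm_i", "imm_memory", 0.85, 0.48, 0.05, 28.0, 7.0, **kw),
        TestDef("lm_ii", "del_memory", 0.85, 0.56, 0.05, 26.0, 7.5, **kw),
        TestDef("bvmt_total", "imm_memory", 0.85, 0.36, 0.07, 25.0, 5.5, **kw),
        TestDef("bvmt_delayed", "del_memory", 0.85, 0.44, 0.07, 9.5, 2.0, **kw),
        TestDef("stroop", "executive", 0.90, 0.20, 0.04, 110.0, 18.0, **kw),
        TestDef("tmt_a", "executive", 0.80, 0.32, 0.04, 26.0, 8.0,
                higher_better=False, **kw),
        TestDef("tmt_b", "executive", 0.85, 0.28, 0.04, 62.0, 20.0,
                higher_better=False, **kw),
        TestDef("digsym", "executive", 0.88, 0.24, 0.04, 52.0, 10.0, **kw),
        TestDef("cfl", "global", 0.65, 0.60, 0.03, 40.0, 11.0, **kw),
        TestDef("mmse", "global", 0.55, 0.66, 0.02, 29.0, 1.2, **kw),
    ]


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The default study conditions: ~1063 subjects, 2-5 visits (median
    3) at ~2.51-year intervals, baseline age ~58 (SD 6.4), 30% male,
    ~26% amyloid-positive in a ~21% biomarker subsample, ~5% incident
    MCI-or-worse."""
    cfg = GeneratorConfig(
        domain_defs=_default_domains(), test_defs=_default_tests(),
        seed=seed, **overrides,
    )
    cfg.validate()
    return cfg
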