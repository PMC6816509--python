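# Methods

`cogvar` evaluates how well candidate longitudinal cognitive outcomes —
twelve raw neuropsychological test scores and thirteen composites built
from them — measure cognitive change in a middle-aged ageing cohort.
Two families of metrics are computed: *longitudinal inconsistency*, the
intraindividual standard deviation (IISD) of model residuals across
visits, and *criterion validity*, the strength of each outcome's
relationship with age and with amyloid-beta (Aβ) burden.  Because the
motivating cohort data are not public, the package ships a synthetic
cohort generator that reproduces the statistical structure the analysis
assumes, so every stage is testable end to end.

## The synthetic cohort

Each subject *i* carries, for each latent cognitive domain *d*
(immediate memory, delayed memory, executive function, plus a weakly
loaded "global" construct for screening-type tests), a trajectory in
latent-SD units:

```
L_id(t) = x_i'β_d + (β_age,d + γ_d A_i)(t − t_ref)
          + u_0id + u_1id (t − t_ref) + ε_idv
```

where `x_i` are covariates (sex, education band, standardized literacy),
`A_i ∈ {0,1}` is amyloid status, `u_0, u_1` are subject random
intercepts and annual slopes, `ε_idv` is visit-level occasion noise
shared by all tests of the domain, and `t_ref = 60` years (a
configurable centring point chosen near the cohort's mean age).  Test
*j* in domain *d* is observed at visit *v* as

```
y_ijv = m_j ± s_j · ( λ_j L_id(t_v) + c_ij + p_j(exposures) + e_ijv )
```

with loading `λ_j`, native mean/SD `m_j, s_j` (the sign is negative for
timed tests where a larger raw value is worse), a *stable test-specific
subject effect* `c_ij` (the "methods effect" that raises test–retest
reliability while capping cross-test correlations), a practice bump
`p_j` indexed by the count of prior battery exposures with
geometrically diminishing increments (retention ratio 0.5, asymptote
twice the first bump), and test-specific error `e_ijv`.

Random intercepts share a general factor (weight 0.55) across all
domains, and the two memory domains share an additional "memory" group
factor (weight 0.55), so within-memory-block correlations clearly
exceed memory-versus-executive correlations while all tests remain
positively intercorrelated — the qualitative structure observed in
comprehensive cognitive batteries.

The AVLT is generated as trial subtotals (trials 1–2 and trials 3–5)
plus a delayed score; the conventional total is the sum of subtotals,
so both the trial-split empirical composites and the standard total
exist, and the total's effective error SD follows from the subtotals'
errors adding in quadrature.

**Default conditions.**  1063 subjects; 2–5 visits with probabilities
(.25, .35, .25, .15) giving median 3; intervisit intervals
N(2.51, 0.40²) years floored at 1; baseline age N(58.2, 6.4²); 30%
male; 38% lower education band; literacy N(107, 9²).  Fixed annual age
slopes are −0.020 SD/yr for both memory domains, −0.040 for executive
(so executive tests show roughly twice the age-related change), −0.015
for the global construct.  The Aβ × age interaction γ is −0.040 SD/yr
for memory and executive domains and −0.020 for the global construct.
Test error SDs are distinct and well spread (0.20 for Stroop up to 0.66
for MMSE, executive lowest), which gives the test-consistency ranking a
known ground truth; the common stable-effect SD (0.40) and loadings
(0.55–0.90) leave that ordering intact.  About 21% of subjects carry
biomarkers (91% PET, 57% CSF availability); a latent amyloid variable
increasing with baseline age is thresholded so ~26% of the subsample is
Aβ-positive, and the continuous markers (PiB DVR up, CSF Aβ42 and
Aβ42/40 down) are monotone transforms of the same latent variable plus
noise.  Roughly 5% of subjects are flagged MCI-or-worse from a
post-baseline onset visit; impairment is driven by a low general
cognitive factor and brings a level drop (−0.4 SD), extra decline
(−0.02 SD/yr) and a 1.6× inflation of occasion noise and test errors —
the mechanism behind the sensitivity analyses.

**What the generator does not emulate.**  Native scores are Gaussian:
no floors/ceilings (MMSE's discreteness and ceiling are not modelled),
no skew in timed tests, no missing visits or item-level missingness, no
dropout related to decline, no cohort attrition or practice
heterogeneity across subjects.  Passing tests therefore demonstrate
that the *pipeline* recovers the structure it assumes, not that real
batteries satisfy these assumptions.

## Scoring and composites

All scores are z-standardized against the *standardizing sample*
(subjects with ≥ 2 complete visits, no baseline neurological diagnosis,
never MCI-or-worse), pooling its person-visits; TMT-A and TMT-B are
multiplied by −1 first.  Pooled (not baseline-only) moments are the
default because they make the restandardized composites have unit SD
over the analysis sample; a baseline-only selector can be passed
instead.  A composite is Σwz/Σw over its component z-scores,
restandardized to mean 0 / SD 1 on the standardizing sample; rows
missing any component are missing (complete-case).  Held-out rows —
e.g., impaired subjects re-admitted to the biomarker subsample — are
scored with the standardizing sample's stored parameters.  The
registry contains five empirically weighted composites (weights are
config inputs; the shipped defaults are synthetic stand-ins, since the
source factor loadings are not public), three equally weighted
theoretical domain composites, and five PACC-style global composites.

## Trajectory models and IISD

Each outcome gets a linear mixed model fit by REML (statsmodels
`MixedLM`): fixed effects for centred age, sex, education band,
literacy and prior exposures, with a per-subject random intercept and
random age slope.  Age is centred at the standardizing sample's mean
and internally rescaled to decades — with annual slopes the random
slope variance is ~1e-4 and the REML surface is so badly scaled that
optimizers routinely fail; in decades every fit converges quickly, and
all reported quantities are rescaled back to per-year units.  Prior
exposures enter categorically by default: a categorical term absorbs
any practice profile indexed by exposure count exactly, keeping the
age slope clean even though the generating practice curve is
non-linear (a linear coding is available).  Wald 95% CIs throughout.
On optimizer failure the model is refit with an intercept-only random
effect (flagged; subject slopes then error with a pointer to the
flag), and as a last resort by OLS with zero variance components —
which is the exact solution in the zero-noise limit.

IISD uses *conditional* residuals (observed − fixed-effect prediction −
predicted random effects): removing the subject's own trajectory leaves
visit-to-visit inconsistency, whereas marginal residuals would fold
stable between-person differences into the metric.  A flag exposes
marginal residuals for comparison.  Per subject and outcome, IISD is
the n−1 sample SD of ≥ 2 residuals (the unbiased-variance convention
matters with 2–5 visits; subjects with fewer are excluded and
counted).  The outcome-level summary is the unweighted mean over
subjects (a visit-count-weighted option exists) with a percentile
cluster bootstrap CI, B = 1000, resampling subjects with replacement,
seeded and deterministic.

## Criterion validity

*Age effects*: the fixed age slope per outcome with its Wald CI.
*Two-stage Aβ model*: covariate effects are removed with the same
covariate-only mixed models as the IISD stage (conditional residuals,
for internal consistency), then the residuals are modelled on Aβ and
Aβ × age with subject random effects; reported as the marginal
generalized R² for mixed models — fixed-effect prediction variance over
(fixed + random + residual), the random-slopes variance term using the
mean squared age covariate; the conditional R² is also emitted.
Because stage-1 BLUPs absorb part of any Aβ-linked slope difference,
this R² is an attenuated, deliberately conservative screen: its null
median is ~1e-3 and it rises monotonically with the generating γ.
*One-stage interaction*: the full model adds the Aβ main effect and
Aβ × age; the interaction's Wald CI is the effect-size display.
*Biomarker–slope correlations*: Spearman ρ between each continuous
marker and per-subject slope estimates (fixed age effect + predicted
random slope; a per-subject OLS option exists).  Slope BLUPs are
strongly shrunken at ~226 biomarker subjects with 2–5 visits, so these
correlations are attenuated (~±0.2 at best) and are most stable for
low-error executive outcomes — a genuine property of the design, not a
defect.  No multiple-comparison adjustment is applied anywhere, by
design.

## Reliability and discriminant validity

The correlogram is pairwise Spearman over person-visits (subject-means
option available).  The MTMM matrix covers nine raw tests in three
theoretical domains: the diagonal is a one-way random-effects ICC
(σ²_between / (σ²_between + σ²_within) from ANOVA mean squares with the
standard unbalanced-design average group size, truncated at zero; no
rater structure is assumed), and off-diagonals are repeated-measures
correlations (pingouin's ANCOVA formulation; df = N_obs − N_subjects −
1), with same-test and same-domain cell annotations.

## Sensitivity analyses

The expanded sample re-admits impaired subjects; standardization and
models are refit from scratch by default (a freeze option scores the
expanded sample with the standardizing parameters).  Reported: mean
IISD per outcome in both samples, their correlation across outcomes,
and the impaired-minus-unimpaired IISD difference.  Risk-group
analyses compare group mean IISD (APOE ε4 carriers, psychiatric
diagnosis, fair/poor health, any clinical diagnosis) against a
lower-risk comparison group (none of the above), with cluster-bootstrap
CIs suppressed below 10 subjects.  Validity sensitivity recomputes
mean IISD, R²_GLMM and the Aβ × age interaction on the biomarker sample
with and without its impaired members and reports Pearson (and
Spearman) agreement across outcomes.

## Problem sizes and numerical choices

The test suite exercises the pipeline at the design's native sizes
where the check depends on them (parameter recovery: 200 replicates at
n = 1063 with a ~226-subject biomarker subsample; ranking recovery at
n = 1000) and at reduced sizes (n = 150–300 subjects) for properties
that are scale-free, such as closed-form oracles and null calibration;
the chosen sizes are stated in each test.  Ties in IISD ranking break
alphabetically.  Bootstrap and generator randomness are fully
determined by explicit seeds; per-subject RNG sub-streams are spawned
from the cohort seed so a subject's realization is independent of
cohort size, and all noise is drawn as standard normals scaled by SDs,
making paired-seed comparisons (e.g., raising one error SD) sharp.

## Known limitations

Empirical composite weights are placeholders, not the published factor
loadings.  The generator's Gaussian native scales overstate how well
MMSE-like bounded scores satisfy the mixed model.  The one-way ICC is
one of several ICC conventions; with strong stable test effects it is
an upper-range choice.  R²_GLMM from conditional residuals understates
absolute effect sizes (comparisons across outcomes remain meaningful).
Biomarker–slope correlations inherit BLUP shrinkage and should be read
as rank screens, not effect sizes.
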