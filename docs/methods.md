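# Methods

## Estimand and model

One *impression* is one person seeing one 10 s interval containing
content in one video they have ever watched. With ever-seen (not
view-count) survey data the estimator counts at most one viewing per
person per video, so the results are a floor on true exposure; a
repeat-view multiplier can be applied externally to the per-capita
output if viewing-frequency data exist.

For stratum *g* and content class *c*:

- `p̄_g` — survey-weighted mean over respondents of the fraction of the
  surveyed videos ever seen. By exchange of summation this equals the
  average over videos of the per-video weighted ever-seen proportion
  (the "Fubini identity" in the tests), so the aggregate and per-video
  routes agree exactly on the point estimate.
- `I_c` — number of coded intervals where any of the class's flags
  (any category, any channel, any substance in the class) is present.
  Union semantics: multiple appearances in a window count once.
- `N_g` — census mid-year population, millions.

Headline results use the aggregate form `G = p̄_g N_g I_c`. The
per-video form `Σ_v p_{g,v} N_g I_{v,c}` is used for the video-level
report; its stratified sum differs from the aggregate form only through
per-video reach variation and is available for cross-checks.

## Variance and confidence intervals

The survey method behind the published table is unstated; this package
uses the standard survey-weighted choice: a normal approximation on the
weighted mean of per-respondent fractions with Kish effective sample
size,

```
n_eff = (Σw)² / Σw²,  se = sqrt( [Σw(f − p̄)²/Σw] / (n_eff − 1) ),
CI = p̄ ± 1.96·se, clipped to [0,1].
```

The `n_eff − 1` divisor makes the estimator collapse exactly to the
ddof = 1 unweighted standard error when weights are equal. Weights are
taken as supplied (panel-calibrated); no re-raking.

CI propagation: `N` and `I` are treated as deterministic multipliers, so
reach CI endpoints scale linearly into gross/per-capita CIs. Aggregates
across disjoint strata sum CI endpoints — the convention the published
Total row follows for independent samples; a root-sum-square combination
(`ci_method="rss"`) is available and is narrower.

## Semantics and conventions

- Interval indices are 0-based half-open windows [10k, 10(k+1)) s; a
  video of duration not divisible by 10 has ceil(duration/10) intervals
  and the trailing short window is a full coding unit.
- Electronic cigarettes are a separate substance, not folded into
  tobacco: the published interval totals (47 tobacco, 6 e-cigarette) are
  reported as distinct figures and their overlap is unstated. A combined
  class (`ContentClass.parse("tobacco+electronic_cigarette")`) is
  available.
- Missing ever-seen answers default to "not seen" (conservative for
  exposure); `missing="drop"` removes the respondent instead.
- Populations are millions end-to-end; the shipped reference table
  carries both the published group aggregates (e.g. adults 49.20 M) and
  the published age bands (which sum to 49.19 M under 2-dp rounding);
  direct entries take precedence over band sums so published aggregates
  are returned verbatim. Consistency checks against published tables use
  an absolute tolerance of 0.02 M (one unit in the last printed place).
- Rendering rounds half-up at the printed precision (2 dp; 1 dp for
  headline comparisons) at output time only; internal values stay full
  precision so the algebraic identities hold exactly.

## Synthetic-data generator

The generator emulates the study conditions: 32 videos totalling 821
intervals; per-interval substance presence at rates 233/821, 47/821 and
6/821 (alcohol, tobacco, e-cigarette), drawn independently per substance
by default with an optional tobacco–alcohol `overlap_rate`; ~2068
adolescent and ~2232 adult respondents with the surveys' female shares;
mean-1 lognormal weights (σ = 0.3, a moderate design effect with
n_eff/n ≈ 0.92, in line with calibrated online panels).

Design choices:

- **Interval totals.** Per-video interval counts are a random
  composition (a 10-interval floor per video plus a multinomial split of
  the remainder), so every realisation totals exactly 821 and the
  expected class totals sit exactly at the calibration targets. Video
  durations are drawn inside the final window so the ceiling rule is
  exercised.
- **Viewing model.** logit p = intercept + age_coef·(age − 14.5) +
  female_coef·[female] + u_video, u_video ~ N(0, 0.5²). The popularity
  random effect makes per-video reach heterogeneous, as per-video
  viewing clearly is in practice. Coefficients (intercept −1.69,
  age slope −0.0575/yr, female boost +0.64) were calibrated by
  numerically solving for the published group means: marginal reach
  0.22 at ages 11–18 and 0.06 at 19+, female above male (≈0.28/0.17 in
  adolescents). Adult ages follow the census band weights, uniform
  within bands, capped at 90.
- **iid demographics.** Ages and genders are drawn iid from the group
  distributions (gender Bernoulli at the survey's female share) rather
  than as fixed quotas. The reach CI assumes iid sampling; quota-fixed
  demographics would remove sampling variance the Kish SE still counts,
  producing structural over-coverage.
- **Seed discipline.** One root seed spawns independent substreams
  (video structure, video effects, demographics, indicators), so
  changing one component's draw count does not perturb the others, and
  fixed seeds give byte-identical output.
- **Gender-split band populations** are not published; the synthetic
  table splits each band's published total by the adolescent/adult
  gender shares, so aggregates reproduce the published margins. The
  function is named and documented as synthetic.

What the generator does *not* emulate: panel recruitment and quota
sampling, region/social-grade structure (region is a pass-through
label), weight–demographic correlation, repeat viewing, recall error,
and the true (unpublished) per-video reach distribution. Passing tests
therefore demonstrate the estimator's correctness and calibration under
its stated sampling assumptions, not robustness to panel artefacts.

## Ground truth for recovery and coverage

`generate_scenario` records two truths. `model_reach` — the weighted
mean of respondents' model-implied viewing probabilities in the realised
sample — is the target of 3-SE point-recovery checks. `population_reach`
— the model-implied group reach marginalised over the demographic
distribution but conditional on the replicate's realised video effects —
is the target of CI-coverage checks: the reach CI does not (and is not
meant to) account for video-level random effects, so coverage is defined
for the estimand the interval actually addresses. Measured coverage over
500 replicates of the full design is ≈95%.

## Problem sizes

The default test suite runs the full study design (32 videos, 4300
respondents) for fixtures and recovery, 300 replicates for the
interval-calibration Monte-Carlo check, and 500 replicates for CI
coverage; the whole suite completes in roughly two minutes on one CPU.

## Known limitations

- The published table's adolescent per-capita cells are internally
  inconsistent at the second decimal (52.11 printed vs 308.19/5.91 =
  52.15; band gross values sum to 308.77 vs the printed 308.19),
  indicating unrounded intermediate reach values we cannot recover;
  identity tests compare at one unit in the last printed place.
- The normal-approximation CI can be poor for strata with very low reach
  and small n; a bootstrap over respondents would be the natural
  extension.
- Annualised exposure extrapolation and behavioural-effect modelling are
  out of scope: the pipeline stops at gross/per-capita impressions at
  the survey date.
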