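# Methods

`ordmisim` is a Monte-Carlo laboratory for one question: how well do common
multiple-imputation (MI) engines recover the log hazard ratios of an
imbalanced 5-level ordinal covariate — the ECOG performance status at cancer
diagnosis — in a Cox proportional-hazards analysis of registry-like survival
data, when that covariate is partly missing?  This note records the models,
the defaults and why they were chosen, the numerical decisions, and what the
synthetic setting can and cannot show.

## The estimand and the replication loop

One replicate of a scenario (sample size N, missingness proportion p,
mechanism MCAR/MAR/MNAR) runs:

1. draw N patients without replacement from a synthetic complete-data
   population;
2. fit the analysis Cox model on the complete sample — its four ECOG
   contrasts (log HR of ECOG 1–4 against ECOG 0) are the *per-replicate
   truth*;
3. delete a fraction p of the ECOG values under the scenario's mechanism;
4. impute with each engine (m = 5 completed datasets), fit the same Cox
   model on each, pool with Rubin's rules; complete-case analysis (CCA) is a
   single fit on the rows with observed ECOG;
5. record pooled estimates, total variances and 95% CIs per contrast.

Per scenario × method × contrast the summaries are the standard
simulation-study measures: absolute bias AB = mean(θ̂ − θ), relative bias
RB = 100·AB / mean(θ), MSE, coverage rate CR of the 95% CI, average CI
width AW, and MCSE(bias) = √(var(θ̂ − θ)/n_sim).  The replication count
follows the planning identity n_sim = ⌈Var(θ̂)/MCSE²⌉; with the planning
values Var ≤ 0.16 (SE 0.4) and a target MCSE of 0.016 this gives 625.

Because the truth is *re-estimated on each complete sample*, RB's
denominator is the mean complete-data estimate of the contrast (the
per-replicate truth varies; several conventions exist and this one is fixed
and documented here).  A consequence worth stating plainly: the pooled
estimate and the complete-data truth share the same sampling noise — only
the missing-data noise separates them — so a 95% CI built from the *total*
variance T mechanically covers the complete-data truth in well over 95% of
replicates at low missingness.  Coverage checks in this package therefore
test "not significantly *below* nominal" (CR ≥ 95% − 3 Monte-Carlo SE);
overcoverage near 100% is the expected signature, not a defect.

## The synthetic registry population

The generator emulates a complete-case lung-cancer registry cohort:

* **Marginals** are calibrated to published complete-case descriptive
  statistics: ECOG prevalences 25.2/48.8/16.3/7.2/2.4%, 58.3% male, age
  68.3 ± 9.5 years, four diagnosis years (19.6/20.3/27.7/32.4%), 12 tumour
  stages, 4 grades, 6 topography and 4 (collapsed) morphology categories,
  and four first-line therapy variables with "no therapy reported" baselines.
  Probability vectors are stored as exact count ratios so they sum to one.
* **Dependence** is a Gaussian copula: a latent-normal core over (age, ECOG,
  stage, grading) with default correlations 0.3/0.4/0.3/0.2/0.25 (moderate,
  configurable), and therapy variables generated from latent scores loaded
  on the ECOG and stage latents (e.g. curative intention loads negatively on
  both).  The real joint distribution is unavailable; dependence is an
  explicit assumption, not an estimate.
* **Survival** follows a Weibull proportional-hazards model (default shape 1
  = exponential) whose linear predictor uses the same design matrix as the
  analysis model.  Default true log-HRs are *package choices, not published
  values*: monotone ECOG contrasts 0.3/0.7/1.1/1.6 (sized so the largest
  contrast's SE at N = 500 is ≈ 0.4, the planning assumption), plus modest
  adjuster effects (age 0.02/year, stage +0.12 per stage step, small-cell
  morphology +0.4, curative intention −0.4, …).
* **Censoring** combines administrative follow-up — 60 months for the first
  diagnosis year minus 12 per later year, minus a uniform within-year entry
  offset — with exponential dropout at 0.014/month.  Scale (345 months) and
  dropout were fixed once by bisecting against the Kaplan–Meier median of a
  generated population (lifelines as the independent oracle) until it hit
  14 months while the death fraction matched 61.4%.  Observed times are
  rounded up to whole months, so tied event times are ubiquitous by design.

A Karnofsky-to-ECOG conversion utility (100/90→0 … 0→5) is included because
registries record either scale.

## Amputation

Missingness is produced by the weighted-sum-score algorithm: per-row score
sᵢ = Σⱼ wⱼ zᵢⱼ over column-standardised variables, deletion probability
logistic(b + sᵢ) (right-tailed: higher score ⇒ more missing), with the
intercept b solved by bisection on [−20, 20] so the mean probability equals
the target proportion (|mean p − p| < 1e-8), then independent Bernoulli
draws — so the realized fraction is stochastic, not exact-count.  MCAR sets
all weights to zero (constant probability); MNAR puts weight 1 on ECOG
itself; MAR uses signed weights on observed variables.  The shipped MAR
default (event +0.5, Nelson–Aalen +0.5, stage +0.3, age +0.2, intention
−0.3) is a plausible stand-in for unavailable data-derived weights; a
`derive_mar_weights` routine reproduces the derivation procedure (one
logistic regression of the missingness indicator on all candidates,
retaining Wald-significant coefficients with their signs).  Whether the
original analysis standardised variables before weighting and which tail it
used is not stated anywhere; both are fixed here as documented assumptions.
Only the ECOG column is ever touched.

## Imputation engines

All engines share one predictor matrix: every analysis covariate plus the
Nelson–Aalen cumulative-hazard estimate and the event indicator in place of
the survival time (the standard outcome-side auxiliaries for survival
imputation).  With exactly one incomplete variable, chained equations
collapse to a single univariate imputation model, so each engine implements
the corresponding univariate defaults directly; m = 5.

* **PMM** — Bayesian linear regression of the numerically coded ECOG;
  type-1 matching (posterior-draw predictions for missing rows, point
  predictions for observed rows); donor = uniform draw among the 5 nearest
  predictions.  Matching is one-dimensional, so donors are found by sorted
  search rather than a full distance matrix.
* **POLR** — cumulative-logit (proportional-odds) ML fit with ordered
  thresholds (log-increment parameterisation), ridge 1e-4, L-BFGS with
  analytic gradients; parameter uncertainty via one nonparametric bootstrap
  refit per imputation, warm-started from the base fit.  Categories absent
  from a bootstrap resample are merged out of the threshold set (logged) and
  receive zero predicted probability.
* **POLYREG** — multinomial logit over the five categories (reference 0)
  with the same weak ridge; bootstrap refit per imputation; categories
  sampled from predicted probabilities.  Unobserved categories get zero
  probability — deliberately mirroring the finite-sample pathology of rare
  top categories.
* **RF** — the chained-equations forest recipe: 10 fully grown
  classification trees (√p features per split) on bootstrap resamples of
  the observed rows; each missing row is routed down one uniformly chosen
  tree and takes the ECOG of one *observed* row (in-bag or out-of-bag)
  drawn uniformly from the reached leaf.
* **JM** — latent-normal joint model: four latent scores (category =
  argmax against 0) regressed on the predictors; Gibbs sampling alternates
  truncated-normal latent draws with a conjugate matrix-normal coefficient
  draw; first imputation after 500 burn-in sweeps, then every 500 sweeps.
  With a single categorical variable the latent residual covariance is not
  identified, so it is fixed at the standard identification constraint
  (unit diagonal, ½ off-diagonal); an `estimate_cov` option restores the
  general inverse-Wishart update (trace-normalised) for completeness, but
  that chain random-walks along the residual unidentified directions and is
  not the default.  The coefficient prior is a proper ridge (λ = 1 on
  standardised predictors): rare-category components see only a few dozen
  "winner" rows and an almost-flat prior makes the data-augmentation chain
  mix pathologically.  Even with the proper prior, rare-category components
  carry autocorrelation times of order several hundred sweeps, so the
  convergence diagnostic (split-chain R̂ < 1.1 of the latent-mean trace)
  monitors a long chain; with the 500/500 default the five imputations are
  valid posterior draws but serially correlated in rare-category directions.
* **CCA** — listwise deletion; flagged as failed when no rows remain or an
  ECOG category loses all its complete cases (the pipeline records such
  replicates as missing entries, never as zeros).

Random-number discipline: every engine consumes an independent stream
derived from (master seed, scenario index, replicate index, engine name), so
engines are comparable within a replicate and results are independent of
scheduling and worker count.

## Survival estimation and pooling

The Cox partial likelihood with the Efron tie correction is maximised by
Newton–Raphson with step-halving (month-resolution times make ties the
norm; the tie method is a documented choice).  Convergence is declared at
|Δ log L| < 1e-12 with a scale-aware gradient safeguard; the fit agrees
with an established survival library to ~1e-7 on tied fixtures.  Constant
adjuster columns (unpopulated categories in small samples) are merged into
the reference level; an absent ECOG category is a structured failure record,
not an exception.  Wald 95% CIs throughout; CCA uses normal quantiles.

Rubin's rules pool the m per-imputation estimates: Q̄, within-variance W,
between-variance B (denominator m − 1), T = W + (1 + 1/m)B, and
Barnard–Rubin degrees of freedom with complete-data df = events − parameters
(small-sample practice; the classical (m−1)(1 + W/((1+1/m)B))² is also
reported).  B = 0 collapses to T = W with normal quantiles.

## Problem sizes in the shipped test-suite

The full-scale study (45 scenarios × 1,000 replicates × 6 methods) is a
multi-day computation; the package's own verification runs at desk scale,
chosen once as its study conditions: coverage calibration at N = 5,000,
MCAR 10%, 100 replicates, all engines; the small-sample ordering property at
N = 1,000, MAR 40%, 200 replicates; engine validity across the
30-scenario desk grid (N ∈ {500, 1,000} × 5 proportions × 3 mechanisms) at
one replicate each; distribution-match checks at N = 5,000 over 50
replicates.  All Monte-Carlo error bands are computed from the replication
counts actually run.

## What the synthetic setting does not show

* The generator's moderate copula correlations give the covariates a much
  weaker hold on ECOG than real registry data have.  One documented
  consequence: the *absolute* downward offset of RF's imputed means
  (mean_imp < mean_obs across all scenarios on registry data) does not
  reproduce here — under outcome-dependent MAR every engine's mean_diff is
  positive because sicker patients' ECOG values are deleted preferentially
  and correctly imputed higher.  What does reproduce is the *relative*
  majority-class pull: RF's imputed mean sits consistently below the
  regression engines' on the same cohort.  Tests assert the relative
  property; the absolute-sign check is retained in the acceptance suite as
  a registry-data-specific expectation and documented as such.
* Published headline numbers (e.g. specific RB percentages per engine and
  scenario) depend on the confidential registry extract and are out of
  reach by construction; the pipeline reproduces the qualitative structure
  (bias growing with missingness and across ECOG categories, rare-category
  instability at small N, near-nominal-or-above coverage).
* MNAR here, as in the original design, behaves MAR-like: ECOG is strongly
  tied to observed survival variables, so weighting the missing value itself
  largely re-weights observed information.  No delta-adjustment sensitivity
  analysis is included.
* Only one variable is ever missing.  Multivariate missingness, time-varying
  effects and proportional-hazards diagnostics are out of scope.
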