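# ordmisim

Monte-Carlo simulation pipeline for **multiple imputation of a missing
ordinal covariate in Cox proportional-hazards survival analysis**, built
around the setting that makes the problem hard in practice: cancer-registry
cohorts where the ECOG performance status (ordinal 0–4, heavily imbalanced,
prevalences ≈ 25/49/16/7/2%) is missing for a sizeable fraction of patients
while overall survival is fully observed.

It is written for biostatisticians and epidemiologists who want to know
*which imputation engine to trust, at which sample size and missingness
level*, before they commit a registry analysis to one of them.

## What it does

The estimand is the vector of log hazard ratios log HR(ECOG = k vs 0),
k = 1…4, from the Cox model

&nbsp;&nbsp;&nbsp;&nbsp;λ(t│x) = λ₀(t) · exp(β₁·1[ECOG=1] + … + β₄·1[ECOG=4] + γᵀz),

with z the registry adjusters (age, sex, stage, grading, morphology,
topography, therapy variables, diagnosis year).  The pipeline:

1. **generates** a registry-like complete population (Gaussian-copula
   covariates calibrated to published complete-case marginals; Weibull
   proportional-hazards survival; administrative censoring by diagnosis year
   plus dropout; times in whole months, so ties everywhere);
2. **samples** N ∈ {500, 1000, 5000} patients without replacement, and takes
   the complete-sample Cox fit as the per-replicate truth θ;
3. **amputes** ECOG with the weighted-sum-score algorithm under MCAR, MAR
   (outcome-dependent, via Nelson–Aalen and event weights) or MNAR at
   10–50% missingness;
4. **imputes** with five engines — predictive mean matching (PMM),
   proportional-odds regression (POLR), multinomial regression (POLYREG),
   random forests (RF), and a latent-normal joint model (JM, Gibbs-sampled
   with 500 burn-in / 500 between-imputation updates) — plus complete-case
   analysis (CCA);
5. **fits** the Cox model on each completed dataset (own Newton solver on
   the Efron partial likelihood, verified against lifelines to 1e-6) and
   **pools** with Rubin's rules (T = W + (1+1/m)B, Barnard–Rubin df);
6. **scores** absolute/relative bias, MSE, coverage and CI width per
   scenario × method × contrast, with Monte-Carlo standard errors, and the
   imputation diagnostics mean_diff = mean(imputed) − mean(observed).

Replication counts follow the planning rule n_sim = ⌈Var(θ̂)/MCSE²⌉
(0.16/0.016² → 625).  See `docs/methods.md` for models, defaults, numerical
decisions and limitations.

## Worked example

```python
import numpy as np, pandas as pd
import ordmisim as om

pop = om.generate_population(om.GeneratorConfig(seed=1))      # 50,000 patients
cohort = om.sample_population(pop, 5000, seed=2)              # one study sample
truth = om.fit_cox(cohort)                                    # complete-data truth

amputed, realized, _ = om.ampute(
    cohort, om.AmputationConfig("MAR", proportion=0.3, seed=3))
print(f"deleted {realized:.1%} of ECOG values")

result = om.impute_polyreg(amputed,
                           predictors=om.build_predictors(amputed), seed=4)
fits = [om.fit_cox(ds, warm_start=truth.params) for ds in result.datasets]
pooled = om.rubin_pool(
    np.stack([f.params[om.ECOG_TERMS] for f in fits]),
    np.stack([f.cov.loc[om.ECOG_TERMS, om.ECOG_TERMS] for f in fits]),
    names=om.ECOG_TERMS, df_complete=fits[0].df_complete)

print(pd.DataFrame({"truth": truth.params[om.ECOG_TERMS].round(3),
                    "pooled": pooled.q.round(3),
                    "ci_low": pooled.ci_lower.round(3),
                    "ci_high": pooled.ci_upper.round(3)}))
```

prints

```
deleted 31.2% of ECOG values
        truth  pooled  ci_low  ci_high
ecog_1  0.304   0.336   0.231    0.441
ecog_2  0.717   0.693   0.524    0.862
ecog_3  1.188   1.172   1.014    1.330
ecog_4  1.436   1.468   1.070    1.867
```

i.e. after deleting 31% of ECOG values under an outcome-dependent MAR
mechanism, multinomial-regression imputation recovers all four log-HR
contrasts of this sample's complete-data fit well within the pooled 95%
CIs — including the rare ECOG = 4 contrast, whose wider interval reflects
the ≈ 2.4% category prevalence.

A full factorial study runs from the command line:

```bash
ordmisim run --nsim 100 --seed 7 --out results/
ordmisim summarize --records results/records.csv
```

which writes tidy per-replicate records, a summary CSV (AB, RB, MSE, CR,
AW, MCSE per scenario × method × contrast) and a manifest with seeds and a
config fingerprint; re-running resumes finished replicates, and results are
identical for any `--workers` count.  `generate`, `ampute` and `impute`
verbs expose the individual stages on CSV files.

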