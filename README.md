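# stabsel

Variable-selection **stab**ility analysis for linear models of HbA1c, built
for epidemiological cohort studies that screen many candidate correlates
(psychosocial scale scores, dietary patterns, anthropometry, genotype) while
keeping a small set of covariates forced into every model.

Stepwise selection applied once to one dataset hides the uncertainty of the
selection itself. `stabsel` makes that uncertainty measurable: it repeats AIC
backward elimination across bootstrap resamples of the cohort and reports,
per variable, how often it survives and what its coefficient looks like once
selection noise is accounted for.

## The method

Given an outcome *y* (HbA1c, %), forced covariates (age, sex, BMI, additive
genotype dose) and candidate covariates, the pipeline evaluates three models:

1. **Global model** — OLS of *y* on all covariates:
   *y* = β₀ + Σⱼ βⱼxⱼ + ε, with classical SEs and t-based 95% limits.
2. **Selected model** — backward elimination from the global model: at each
   step, drop the non-forced term (categorical variables move as whole
   indicator blocks) whose removal most decreases
   AIC = n·ln(RSS/n) + 2k + n·ln(2π) + n;
   stop when no removal decreases AIC. For a single-parameter step this is a
   likelihood-ratio test at p = P(χ²₁ > 2) ≈ 0.157. Forced covariates are
   never eligible.
3. **Bootstrap stability investigation** — repeat the elimination on B
   (default 1000) resamples of size n drawn with replacement, and report
   per variable:
   - **inclusion frequency** (BIF): percent of resamples in which the
     variable is selected (forced covariates sit at 100 by construction);
   - **final bootstrap estimate** β̂ᵦ: the median across *all* resamples of
     the coefficient, with 0 substituted when the variable was eliminated,
     plus 2.5th/97.5th percentile limits of the same vector (read as a 95%
     interval) and a standardised version β̂ᵦ·SD(x)/SD(y);
   - **RMSD ratio**: √(mean((bᵢ − β̂_global)²)) / SE(β̂_global), zeros
     included — values above 1 flag selection-added variability;
   - **RC bias**: 100·(mean(bᵢ | selected)/β̂_global − 1), the percent bias
     of the coefficient conditional on having been selected;

   and globally the **selected-model frequency** (percent of resamples that
   choose exactly the original selected set) and a **shrinkage factor** (the
   cross-validated calibration slope of the selected model; < 1 means the
   apparent fit overstates out-of-sample performance).

Variables with BIF > 60% are flagged as meaningful in the run manifest.

The surrounding pipeline covers the standard preprocessing steps: Likert
scale scoring with reverse-coding and within-domain (person-mean) imputation
applied only when an instrument's cohort missingness falls in a 5–10% band;
dietary pattern scores from food-frequency data (residual-method energy
adjustment, principal-component extraction of the group correlation matrix,
varimax rotation, regression-method scores standardised to mean 0 / SD 1);
and typed cohort CSV I/O with HbA1c categorisation (≥ 6.5% diabetes,
5.7–< 6.5% prediabetes). A seeded synthetic-cohort generator emulates the
target study's structure so the whole pipeline runs without any data access.

## Worked example

```python
import stabsel as ss

table = ss.generate_cohort(ss.default_config(n=349, seed=1))
spec = ss.ModelSpec.from_meta(table.meta)        # roles: outcome/forced/candidate
result = ss.bootstrap_stability(table, spec, B=1000, seed=1)

cols = ["beta_global", "inclusion_frequency", "beta_b", "pct_2_5", "pct_97_5", "std_beta_b"]
rows = ["age", "genotype", "abdominal_circumference", "social_support",
        "self_esteem", "diet_mixed_traditional"]
print(result.summary.loc[rows, cols].round(3))
```

```
                         beta_global  inclusion_frequency  beta_b  pct_2_5  pct_97_5  std_beta_b
variable
age                            0.016                100.0   0.016    0.010     0.022       0.172
genotype                      -0.293                100.0  -0.291   -0.359    -0.221      -0.246
abdominal_circumference        0.038                100.0   0.037    0.029     0.046       0.667
social_support                 0.212                 98.9   0.214    0.100     0.314       0.121
self_esteem                    0.006                 33.3   0.000    0.000     0.021       0.000
diet_mixed_traditional        -0.167                100.0  -0.166   -0.222    -0.111      -0.183
```

The forced covariates (`age`, `genotype`, plus `sex` and `bmi` not shown)
have inclusion frequency exactly 100. `self_esteem` is a pure-noise
candidate in this synthetic cohort: it survives in only a third of the
resamples, so its final bootstrap estimate is exactly 0 under the
zero-substitution convention, with the percentile interval pinned at 0 on
one side. The generator's nonzero effects (allele dose −0.339 per A copy,
age +0.020 per year, and so on) are recovered at the right scale by both the
global estimates and the bootstrap medians.

The same analysis from the shell:

```bash
stabsel simulate --n 349 --seed 1 --out cohort.csv
stabsel run --data cohort.csv --meta cohort.meta.yaml -B 1000 --seed 1 --out results/
stabsel stratify --data cohort.csv --meta cohort.meta.yaml --stratum sex -B 1000 --seed 1 --out results/by_sex/
```

`run` writes a stability table (CSV + markdown), a full-precision
`results.json`, and a `manifest.json` recording the seed, B, analysed n,
imputed variables and flagged (> 60% BIF) variables.

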