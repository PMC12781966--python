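# Methods

This note documents the statistical procedures implemented in `stabsel`, the
choices made where the methodology was genuinely open, and what the synthetic
data can and cannot establish.

## Models and selection rule

All models are ordinary least squares with main effects only. The global
model contains every forced and candidate covariate; the selected model is
reached by pure backward elimination (no re-entry) from the global model.

**AIC convention.** AIC = n·ln(RSS/n) + 2k + n·ln(2π) + n, the full Gaussian
log-likelihood form with constants, where k counts estimated mean parameters
including the intercept. The constants cancel in comparisons; including them
matches the output of mainstream statistical software, and the test suite
cross-checks the value against −2·(maximised Gaussian log-likelihood) + 2k.

**Elimination step.** At each step the procedure evaluates the removal of
every non-forced term and removes the one with the largest AIC decrease,
stopping when no removal decreases AIC. Removing one parameter lowers AIC
exactly when the likelihood-ratio statistic n·ln(RSS_r/RSS_f) is below 2,
i.e. when its LR p-value exceeds P(χ²₁ > 2) ≈ 0.1573 — the familiar "0.157
significance level" of AIC-based stepwise selection. Categorical variables
are removed or retained as whole indicator blocks using the block's joint
AIC change (for a two-indicator block the implicit threshold is the χ²₂ tail
at 4, not 0.157). Ties in AIC (a measure-zero event on continuous data) are
broken by removing the term with the smaller (block-maximum) absolute
t-statistic, then lexicographically by name, so elimination paths are
deterministic and order-invariant.

**Numerics.** Reported fits (global and selected) go through statsmodels OLS
with classical covariance and t-based 95% limits. The elimination loop —
which runs up to a few hundred reduced fits per resample — instead solves
normal equations on a precomputed Gram matrix (Cholesky per column subset;
RSS = y'y − c'β). A rank-deficient design raises an error naming the
collinear columns (QR with pivoting); a perfect fit (RSS = 0) is treated as
dominating every comparison, so no term is removed from it. VIFs use the
standard 1/(1 − R²ⱼ) auxiliary-regression form; perfect collinearity reports
an infinite VIF rather than an exception.

## Bootstrap stability investigation

The resampling unit is the participant row: each of the B resamples draws n
rows with replacement and reruns the elimination with the same forced set.
A resample whose design has a constant column or a singular Gram matrix is
redrawn (and counted), so percentile denominators stay at exactly B; a
redraw rate above 5% triggers a warning. With the default generator and
n = 349 redraws are essentially never needed.

Summary definitions follow the glossary in the README. Deliberate pinned
choices, since each affects bit-level reproducibility:

* percentiles and medians use linear interpolation between order statistics
  (numpy's default, Hyndman–Fan type 7);
* standardised coefficients use full-analysis-sample SDs (ddof = 1), not
  per-resample SDs, so each variable gets a single Std. β̂ᵦ;
* RMSD ratio and RC bias are computed for forced covariates too (their
  coefficient vectors simply contain no zeros);
* RC bias is undefined (reported missing) when the global estimate is
  exactly 0 or the variable is never selected;
* all randomness flows from one `SeedSequence`, spawned into separate
  streams for the bootstrap and the cross-validation folds, so identical
  seeds give bit-identical results.

**Shrinkage factor.** The paper-style "shrinkage" here is the calibration
slope: the outcome is regressed on the out-of-fold linear predictor of the
selected model under 10-fold cross-validation (fold assignment seeded,
configurable down to leave-one-out). The cross-validated predictor uses the
covariate part only; the training-fold intercept tracks the fold mean, which
is anticorrelated with held-out outcomes and would bias the slope downward
under the null, while the second-stage regression has its own intercept so
the predictor's location is irrelevant. Under a strong signal the slope
approaches 1; under pure noise it is centred at 0 but heavy-tailed (its
denominator is the variance of a near-constant predictor), which is why the
test suite summarises null replicates by their median.

## Scale scoring and within-domain imputation

Instruments are scored by summing (or averaging, e.g. MSPSS) item responses
after reverse-coding negatively worded items via r → min + max − r. The
instrument definitions validate that the declared score range is attainable
from the item ranges.

"Within-domain imputation" is implemented as respondent-level person-mean
imputation inside the instrument: a missing item is replaced by the mean of
the respondent's observed items (in reverse-coded space), provided at least
half the items are observed. Imputation is applied only when the
instrument's cohort-level missingness lies in the 5–10% band — below it the
handful of incomplete scores are left missing (complete-case), above it the
instrument is considered too incomplete to patch. The person-mean rule is
one standard reading of domain-level imputation for Likert scales; the
policy object (band edges, minimum observed fraction) records the choice and
admits alternatives. Imputed scores are guaranteed to stay inside the score
range, the operation is idempotent, and every imputed cell is logged.
Respondents still missing a score after imputation are dropped at modelling
time (complete-case analysis).

## Dietary patterns

Group intakes are energy-adjusted by the residual method: per group, intake
is regressed on total energy and replaced by residual + predicted intake at
mean energy (equivalently x − b·(e − ē)), which zeroes the intake–energy
correlation while preserving group means. Pattern extraction is the
principal-component method on the group correlation matrix; the leading
three components (a parameter) are varimax-rotated. Because eigenvectors are
sign-ambiguous, each rotated factor is flipped so its largest-magnitude
loading is positive. Participants are scored by the regression method
(weights R⁻¹Λ on standardised intakes) and scores are standardised to
mean 0 / SD 1 on the fitting sample. Correlation-based extraction makes the
scores invariant to per-group linear rescaling of intakes. Food grouping is
supplied by the user; the synthetic generator ships a 12-group fixture.

## Synthetic cohort generator

The generator is the study-conditions stand-in: n = 349, 53% female,
genotype dose multinomial at 43/40/17% (0/1/2 A copies), continuous
covariates at the published mean/SD clipped to instrument ranges (fat mass
index uses mean 14.0, consistent with the published sex-specific means), a
planted BMI–abdominal-circumference correlation of 0.9 to exercise the VIF
diagnostic, and three N(0, 1) dietary pattern scores. The outcome is linear:
HbA1c = β₀ + Σβx + N(0, 0.54), floored at 4.0%. The nonzero coefficients
default to the published final bootstrap estimates (age 0.020, allele dose
−0.339, abdominal circumference 0.035, stress 0.032, social support 0.320,
self-efficacy −0.024, mixed-traditional diet −0.120); all other candidates
are pure noise. The noise SD was solved once, analytically, so the marginal
HbA1c SD is ≈ 0.9, and the intercept is solved from a target mean of 6.0%.

What the generator does **not** emulate: the real covariates' joint
correlation structure (beyond the one planted pair), the genotype-stratified
sampling design, household/village clustering, skewed score distributions
(scores are clipped Gaussians), and any nonlinearity or interaction.
Because the published effect sizes are imposed on (mostly) independent
covariates, the synthetic signal-to-noise is higher than in the real study
(synthetic R² ≈ 0.67 versus the published 0.19), which makes selection of
the true effects *easier* here. Passing tests therefore establish the
correctness and invariants of the machinery — forced covariates always at
100% inclusion, median-zero below 50% inclusion, percentile sandwiches,
oracle-exact OLS/AIC, seeded reproducibility, recovery of planted effects —
not that the procedure would select the same variables in the real cohort.

Problem sizes used by the automated checks: the study-scale invariant runs
use n = 349 with B = 1000; the parameter-recovery experiment uses 20
replicate cohorts at n = 349 with B = 200; dietary-pattern recovery uses
n = 600 with 12 groups in 3 blocks. These sizes give stable summaries while
keeping a full run in seconds.

## Known limitations

* Stepwise direction is backward-only; no re-entry, no best-subset search.
* No GLMs, robust/sandwich errors, interactions, or multiple imputation.
* Percentile intervals are plain (no BCa correction); the zero-substitution
  convention pins interval endpoints at 0 for sporadically selected
  variables, which is a feature of the reporting convention, not a bug.
* The shrinkage estimator is one defensible choice among several; published
  shrinkage values from other software are not directly comparable.
* The 60% inclusion-frequency rule is a reporting flag, not a selection
  step: it marks variables in the manifest and changes nothing upstream.
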