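# Methods

This note documents the statistical machinery in `cohortmi`, the choices
made where the design was genuinely open, and what the synthetic-data
experiments do and do not establish.

## Cohort model and eligibility

A cohort is a member × variable grid plus a member × sweep status grid with
four codes: respondent (R), non-respondent (N), dead (D), emigrated (E).
Sweep numbering is 1-based with sweep 1 the birth sweep; sources that number
waves from 0 map to this scheme by adding one. Death is always absorbing;
emigration is absorbing by default (returns are not modelled) but the check
can be relaxed on read. The *eligible sample* at sweep *t* is everyone with
status R or N — the target population of members alive and resident — so
`eligible = total − dead − emigrated` and non-response rates are always
quoted relative to the eligible sample. The non-response indicator is 1 for
N, 0 for R and undefined (excluded) for D/E. *Prior participation* is the
single binary "missed any earlier sweep while eligible", not one indicator
per sweep.

Files are plain CSV: value columns plus one `status_sweep<k>` column per
sweep, with a configurable sentinel (default: empty cell) for missing
values; internally missingness is an explicit NaN mask, never a code.
Floats are written as shortest round-trip representations and parsed with
the correctly rounded parser, so write→read is bit-exact.

## Screening

Rules, in order, each recorded per variable and never raised as an error:
routed questions excluded; constituents excluded when their composite is in
the pool; variables missing for more than `max_missing_fraction` (default
0.40) of the members **eligible at the variable's origin sweep** excluded
(the per-sweep eligible sample is the natural denominator; wave non-response
at the origin sweep therefore counts as missingness); binaries with
minority-class prevalence below `min_binary_prevalence` (default 0.01)
excluded — prevalence is one-sided in neither direction, since a 99.5%-one
binary is as uninformative as a 0.5%-one; categorical/ordinal variables with
any level below `min_category_fraction` (default 0.01) recoded when
possible, ordered levels merging into the better-populated adjacent
neighbour and unordered levels into the mode, iterating until no level is
sub-threshold; a two-level variable that cannot merge is excluded. Relaxing
thresholds can only grow the kept set (tested property).

## Modified Poisson regression

Risk ratios for the binary non-response indicator come from a Poisson
working model with log link — chosen over logistic regression because the
risk ratio is collapsible while the odds ratio is not, which matters once
non-response exceeds ~30%. Because the Poisson variance is misspecified for
a Bernoulli outcome, all inference uses the HC0 sandwich
`V = A⁻¹ B A⁻¹` (A the information matrix, which for the canonical log link
equals the observed Hessian; B the summed outer products of scores). No
small-sample correction is applied: the intended sample sizes are in the
thousands. Estimation is statsmodels' IRLS (`tol 1e-8`, ≤100 iterations)
behind a thin wrapper that drops incomplete rows (counting them), checks the
design rank up front — a rank-deficient design raises an error naming the
collinear columns — and flags non-convergence (e.g. separation) in the
result rather than returning a silent estimate. On a saturated two-group
model the estimate reduces exactly to the ratio of group proportions with
sandwich SE `sqrt((1−p₁)/(n₁p₁) + (1−p₀)/(n₀p₀))`, which the tests verify
against a brute-force score-outer-product computation. Wald p-values and
95% CIs use the standard normal quantile.

Categorical covariates are reference-coded with the first listed category
(conventionally the most disadvantaged) as reference. Variable-level
keep/drop decisions in the selection stages use the minimum level-wise Wald
p-value: this mirrors reporting that marks whole variables significant when
any level is, and keeps the decision rule identical across stages.

## Three-stage auxiliary-variable selection

For non-response at target sweep *t*, candidates are the screened variables
from origin sweeps 1..t−1:

* **Stage 1** — one univariable complete-case fit per candidate; keep if
  p < 0.001. Non-converged fits are excluded with a logged reason.
* **Stage 2** — one multivariable complete-case model per origin sweep with
  all of that sweep's stage-1 survivors; keep if p < 0.05. Collinear terms
  are pruned later-entered-first and logged. Complete-case sets are
  per-model (pairwise deletion across models).
* **Stage 3** — the retained variables plus the a-priori set are multiply
  imputed over the eligible sample, with the fully observed non-response
  indicator appended to every imputation model as a predictor (never
  imputed). For each origin sweep *s*, non-response is regressed on the
  sweep-*s* variables adjusted for all retained and a-priori variables from
  earlier (never later) sweeps, once per completed dataset; coefficients
  are pooled by Rubin's rules and a variable is kept if its pooled p < 0.001.
  With no missingness among the model variables the stage degenerates to a
  single complete-data fit with zero between-imputation variance. Collinear
  pruning is done once, on the first completed dataset, so the design is
  identical across imputations and pooling lines up.

Sex, country of birth, father's socioeconomic status and prior participation
skip stages 1–2 and enter stage 3 a priori; by default they are also
force-retained into the final auxiliary set regardless of their stage-3
p-value (configurable), since they are reported alongside the data-driven
predictors even when not significant at some sweeps. Thresholds are strict
(<). All three thresholds, the a-priori list, and the stage-3 adjustment
rule ("earlier-sweep survivors plus all a-priori variables" — one of two
defensible readings of adjusting for previous sweeps) are configuration.

A **consistent predictor** over a period of sweeps (defaults: early 2–4,
late 5–10) is one selected at strictly more than half of its *possible*
target sweeps — sweeps in the period, covered by the supplied traces, and
after the variable's origin sweep.

## Multiple imputation engine

Chained equations over the incomplete variables in order of increasing
missingness fraction, initialised by draws from each variable's observed
margin. Conditional methods by type:

* continuous — **predictive mean matching** (default, 5 donors, type-1
  matching with a Bayesian-drawn β), robust to non-normal score
  distributions because imputations are observed donor values; or a proper
  Bayesian **normal-linear** draw (posterior σ² via scaled inverse-χ², β
  from its normal posterior), which the delta-shift algebra below requires
  exactly;
* binary — logistic regression fit on a bootstrap resample of the observed
  rows (the bootstrap propagates parameter uncertainty), Bernoulli draws
  from fitted probabilities; perfect prediction triggers a ridge-stabilised
  refit (C = 1), logged;
* categorical — multinomial logistic, same bootstrap scheme, draws from the
  fitted class probabilities;
* ordinal — predictive mean matching on the numeric codes: donors are
  observed codes, so imputed values are always valid levels. (A
  proportional-odds conditional was considered and rejected to keep the
  engine dependency-light; PMM-on-codes is the other standard treatment.)

Defaults `m = 20` imputations and 10 cycles are deliberately prominent
configuration, not buried constants; the simulation experiments use smaller
m (3–10) because their estimands are means of many replicates. Observed
cells are never altered; the whole procedure is deterministic given the
seed (one spawned child stream per imputation); imputing data with no
missingness returns m identical copies, and pooling then reproduces the
complete-data estimate and SE exactly.

Rubin pooling: point = mean of per-imputation estimates, `W` = mean
within-imputation variance, `B` = between-imputation sample variance
(exactly 0 for exactly identical estimates), `T = W + (1+1/m)B`, classic
degrees of freedom `(m−1)(1 + W/((1+1/m)B))²` with a normal reference when
B = 0. Ratio-scale quantities (risk and hazard ratios) are pooled on the
log scale and exponentiated for reporting.

**Delta adjustment** adds δ to every *imputed* (never observed) value of a
continuous target variable, per stratum if requested, representing a
not-at-random departure. Under normal-linear imputation with a fixed seed
the pooled mean is exactly linear in δ with slope equal to the missing
fraction, so **calibration** — bisection on δ until the pooled mean matches
an external benchmark, tolerance 1e-3 on the mean scale, the same MI seed at
every evaluation — converges cleanly; an unreachable benchmark raises an
error reporting the attainable range. Under donor matching the shift is
approximate and calibration still applies but with Monte-Carlo wobble.

## Travel-back validation

For an early-sweep estimand and a later target sweep, three estimates are
compared on consistently defined samples: *truth* on all members alive and
not emigrated at the target sweep (the primary comparator, since it matches
the target population; the all-members version can be obtained by passing an
earlier target), *complete case* on the target sweep's respondents, and *MI*
after setting the estimand values of the non-respondents to missing and
imputing them from the chosen auxiliaries plus the non-response indicator.
Reported per quantity: all three estimates with SEs, `bias_cc`, `bias_mi`,
and `relative_bias_reduction = 1 − |bias_mi|/|bias_cc|` (undefined when
`bias_cc = 0`). With zero non-response the three arms coincide exactly.

Estimands: means; category percentages (pooled on the percentage scale;
levels of a variable sum to 100 in every arm); and Cox hazard ratios of a
categorical exposure on later mortality, adjusted for covariates, with
optional left truncation (entry at a given age, e.g. restricting to deaths
after the age-26 sweep). Cox fitting is lifelines' partial-likelihood
maximiser; ties are handled by Efron's method, which coincides with the
exact partial likelihood on untied data (the oracle tests use untied data).
Exposure levels with no events have a monotone partial likelihood and are
dropped from the comparison with a warning. The cognitive composite is the
first principal component of the standardised test scores among members with
all components observed, rescaled to mean 0 / SD 1 with its sign fixed to
correlate positively with the first component; constant components are
dropped with a warning.

## Synthetic cohorts

The simulator emulates the structural features of a 1970s British birth
cohort: ~10 sweeps; baseline sex, six-level paternal social class, parity
(0–4+), four-level country of birth, parental marital status and father's
education-age band; four age-5 test scores sharing a latent ability factor
(pairwise correlation 0.5, ability correlated 0.25 with social class);
household moves and a later voting indicator; per-sweep deaths (exponential
survival with a log-linear class gradient, hazard ratio ≈0.89 per class
step, ≈5% dead by the final sweep) and emigration (0.3%/sweep) as competing
absorbing states; pools of null noise variables, routed parent/child pairs
(child structurally missing when the parent binary is 0) and rare binaries
with prevalence drawn in [0.1%, 3%] to straddle the screening threshold.

Non-response is generated **on the log-risk scale** so generation and
analysis share the risk-ratio parameterisation:
`P(N) = min(exp(intercept_t + Σβx [+ β_prior·prior + β_mnar·x_mnar]), 0.99)`.
Under MAR only values actually collected (member responded at the
variable's origin sweep) contribute; under MNAR a designated variable
contributes through its true, possibly unobserved value. Default effect
sizes mimic published magnitudes (risk ratios ≈0.7–1.5 across a variable's
range; prior non-response RR ≈1.8), and default marginal non-response
targets follow the published participation profile (≈25–48% after the
parent-interview era). The per-sweep intercept is calibrated with a
log-mean-exp correction against the realised covariate distribution so the
marginal rate matches the target. Item missingness (default 3%) is applied
after response status: respondents can still have sporadic missing values.
The ground-truth record (intercepts, per-member linear contributions,
pre-masking values) reproduces every generated probability exactly, and
identical configs give byte-identical cohorts. The simulator makes no
attempt to match any real cohort's joint covariate distribution — only its
structure — and models a closed cohort (no late-entry members); passing
tests on it demonstrate the *methods'* operating characteristics, not
properties of any real dataset.

## Simulation experiments (problem sizes)

The experiments in `cohortmi.experiments` use sizes chosen for stable
Monte-Carlo summaries on one CPU in a few minutes:

* stage-1 calibration: 2 000 null variables in cohorts of 10 000 under
  MCAR(0.3); the keep rate is compared with 0.001 within 3 binomial SEs;
* recovery: 50 cohorts of 10 000 with 8 true predictors (|log RR| = 0.25,
  a magnitude at which stage-1 power is essentially 1 at this n — effects
  much below 0.1 are not recoverable at p < 0.001 by design) and 50 noise
  variables, all fully observed at baseline so stage 3's MI degenerates to
  its complete-data limit; MI with real missingness is exercised separately
  by the restoration experiments;
* restoration: 100 cohorts of 2 000 per mechanism, non-response rate 0.45 at
  the target sweep, MAR driven by an observed test score (log RR 0.5 per SD)
  whose correlation with the estimand (0.5) makes the complete-case bias
  ≈0.18 SD, an order of magnitude above Monte-Carlo noise; the MNAR negative
  control drives non-response by the estimand itself while offering only
  uninformative auxiliaries, so MI cannot and should not help;
* delta: n = 2 000, 40% MCAR missingness, normal-linear method (required for
  the exact shift identity).

## Known limitations

Binary/categorical conditionals propagate parameter uncertainty by
bootstrap rather than an exact posterior draw; Rubin df is the classic
large-sample formula (no small-sample correction); no proportional-odds
conditional for ordinals; no inverse-probability-weighting or
full-information-maximum-likelihood alternatives; no multilevel imputation;
emigration returns and late cohort entry are not modelled; Cox ties use
Efron's approximation only.
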