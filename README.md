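# cohortmi

Tools for handling **wave non-response in multi-sweep birth cohorts**:
selecting auxiliary variables that predict non-response, restoring sample
representativeness with multiple imputation, and stress-testing the
missing-at-random assumption against external benchmarks.

## The problem

Longitudinal population surveys lose participants at every sweep. By
mid-adulthood, around half of a birth cohort's surviving, resident members
may no longer take part, and the members who drop out differ systematically
from those who stay (disadvantaged background, lower childhood cognitive
scores, prior non-response, ...). Analyses restricted to respondents are then
biased. Principled missing-data methods (multiple imputation in particular)
can remove that bias under a missing-at-random (MAR) assumption — but only
if the imputation model includes the variables that actually drive
non-response. `cohortmi` implements a data-driven workflow for finding and
using those variables:

1. **Cohort accounting** (`cohortmi.cohort`) — per-sweep vital status
   (respondent / non-respondent / dead / emigrated), eligible samples
   (total − dead − emigrated), non-response indicators, prior-participation
   derivation.
2. **Screening** (`cohortmi.screening`) — reduce a large variable pool by
   structural rules: drop routed questions and constituents of composites,
   binaries with minority-class prevalence < 1%, variables > 40% missing;
   recode categories below 1%.
3. **Risk-ratio regression** (`cohortmi.poisson`) — modified Poisson
   regression: a log-link Poisson working model for the binary non-response
   indicator with robust sandwich variance `A⁻¹BA⁻¹`, giving collapsible
   risk ratios `RR = exp(β)`.
4. **Three-stage selection** (`cohortmi.selection`) — per target sweep *t*:
   univariable screens at p < 0.001, per-origin-sweep multivariable models at
   p < 0.05, then MI-based multivariable models pooled by Rubin's rules at
   p < 0.001. Sex, country of birth, father's socioeconomic status and prior
   participation enter stage 3 a priori. A *consistent* predictor is one
   selected in more than half of its possible target sweeps within a period.
5. **Multiple imputation** (`cohortmi.mi`) — chained equations for
   mixed-type data (predictive mean matching, Bayesian normal-linear,
   bootstrap logistic/multinomial), Rubin pooling
   (`T = W + (1 + 1/m)·B`), and **delta adjustment**: shift imputed values
   by δ, or calibrate δ so a pooled mean matches an external benchmark.
6. **Validation** (`cohortmi.validation`) — "travel back in time": compare
   truth (everyone alive and resident at the target sweep), complete-case
   (respondents only), and MI estimates of an early-sweep quantity — a mean,
   a category percentage, or Cox hazard ratios with left truncation.
7. **Synthetic cohorts** (`cohortmi.simulate`) — generate 10-sweep cohorts
   with configurable MCAR/MAR/MNAR response mechanisms on the log-risk
   scale, competing deaths/emigration, routed questions, rare binaries and
   item missingness, with full ground truth for every generated probability.

## Worked example

`examples/05_travel_back_validation.py` builds an 8 000-member synthetic
cohort, forms a cognitive composite (first principal component of four
correlated age-5 test scores), and asks whether MI with socio-economic
auxiliaries restores the composite's mean after discarding the final sweep's
non-respondents:

```
estimand: mean of cognitive (target sweep 10)
  mean(cognitive)   truth=   0.0090  cc=   0.0499  mi=  -0.0097  bias_cc=+0.0409  bias_mi=-0.0186

complete-case bias +0.041 SD; after MI -0.019 SD (bias reduction 54%).
```

The respondents of sweep 10 over-represent high scorers (complete-case mean
+0.05 SD above the population value); imputing the non-respondents' scores
from the auxiliaries moves the estimate back within Monte-Carlo error of the
truth. The other examples cover cohort accounting, screening, risk-ratio
regression (`rr`, robust 95% CI per covariate), the three-stage selection
audit, and delta calibration against an external benchmark.

A thin CLI mirrors the library (`cohortmi simulate | screen | select |
impute | calibrate-delta | validate | run`); `cohortmi run --config run.yaml`
executes the whole pipeline and writes a manifest with the config hash and
seed, so reruns are byte-identical.

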