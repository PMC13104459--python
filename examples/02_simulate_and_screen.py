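"""Simulate a multi-sweep cohort and screen its variable pool.

The simulator emulates a birth cohort with socio-economic baseline
covariates, correlated early test scores, attrition driven by known
predictors, routed questions and rare binaries.  Screening then applies the
structural eligibility rules (routing, prevalence, missingness, small
categories) and records a decision for every variable.
"""

from cohortmi import SimConfig, participation_summary, screen, simulate

cohort, truth = simulate(SimConfig(n_members=5000, seed=42, n_noise_vars=30))

print("participation by sweep:")
print(participation_summary(cohort)[["eligible", "respondents", "nonrespondents"]])

res = screen(cohort)
print("\nscreening decisions:")
print(res.counts().to_string())
print(f"\n{len(res.kept)} of {len(cohort.values.columns)} variables remain "
      "as candidate predictors of non-response.")
print("true non-response predictors in this simulation:",
      ", ".join(truth.true_predictor_names))
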