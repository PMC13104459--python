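"""Travel-back-in-time validation: does MI restore representativeness?

An early-childhood cognitive composite (first principal component of four
correlated test scores) is estimated (i) on everyone alive and resident at
the target sweep, (ii) among that sweep's respondents only, and (iii) after
multiply imputing the non-respondents' scores with auxiliary variables.
Under attrition driven by observed covariates, the complete-case mean is
biased upward and MI pulls it back toward the truth.
"""

from cohortmi import (
    Estimand,
    MIConfig,
    SimConfig,
    composite_score,
    simulate,
    travel_back,
)
from cohortmi.cohort import VariableMeta
from cohortmi.simulate import TEST_SCORES

cohort, _ = simulate(SimConfig(n_members=8000, seed=3))

# cognitive composite from the four age-5 test scores
cohort.values["cognitive"] = composite_score(cohort.values[list(TEST_SCORES)])
cohort.meta["cognitive"] = VariableMeta("cognitive", 2, "continuous")

report = travel_back(
    cohort,
    Estimand(kind="mean", variable="cognitive"),
    target_sweep=cohort.n_sweeps,
    auxiliaries=["father_social_class", "sex", "parity", "household_moves",
                 "prior_incomplete"],
    mi_config=MIConfig(m=10, n_iterations=3, seed=1),
)
print(report.render_text())
r = report.rows[0]
print(
    f"\ncomplete-case bias {r['bias_cc']:+.3f} SD; after MI {r['bias_mi']:+.3f} SD "
    f"(bias reduction {100 * r['relative_bias_reduction']:.0f}%)."
)
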