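import numpy as np
import pandas as pd
import pytest

from cohortmi import CohortTable, SimConfig, VariableMeta, simulate


def make_toy_cohort(status_rows=None):
    """3 members, 2 sweeps, one death at sweep 2; one all-missing column."""
    values = pd.DataFrame(
        {
            "age_mother": [24.0, 31.0, 28.0],
            "lowbw": [0.0, 1.0, np.nan],
            "empty_var": [np.nan, np.nan, np.nan],
        },
        index=pd.Index(["m1", "m2", "m3"], name="member_id"),
    )
    status = pd.DataFrame(
        status_rows
        if status_rows is not None
        else [["R", "R"], ["R", "N"], ["R", "D"]],
        index=values.index,
        columns=[1, 2],
    )
    meta = {
        "age_mother": VariableMeta("age_mother", 1, "continuous"),
        "lowbw": VariableMeta("lowbw", 1, "binary"),
        "empty_var": VariableMeta("empty_var", 1, "continuous"),
    }
    return CohortTable(values, status, meta)


@pytest.fixture
def toy_cohort():
    return make_toy_cohort()


@pytest.fixture(scope="session")
def sim_cohort():
    """A mid-size default-condition cohort shared across read-only tests."""
    cohort, truth = simulate(SimConfig(n_members=4000, seed=123))
    return cohort, truth
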