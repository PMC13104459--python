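"""Composite score, Cox partial likelihood, travel-back reports."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from cohortmi import (
    Estimand,
    MIConfig,
    MortalityModel,
    SimConfig,
    VariableMeta,
    composite_score,
    fit_cox,
    simulate,
    travel_back,
)
from cohortmi.errors import ConfigError


class TestCompositeScore:
    def test_duplicated_component_reduces_to_standardised_variable(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(500)
        df = pd.DataFrame({"a": x, "b": x, "c": x})
        s = composite_score(df)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(
            s.to_numpy(), (z - z.mean()) / z.std(ddof=1), atol=1e-10
        )

    def test_two_uncorrelated_components(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"a": rng.standard_normal(4000), "b": rng.standard_normal(4000)}
        )
        s = composite_score(df)
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.std(ddof=1) == pytest.approx(1.0, rel=1e-9)

    def test_equicorrelated_loadings_match_eigen_oracle(self):
        rng = np.random.default_rng(2)
        n = 5000
        g = rng.standard_normal(n)
        comps = {
            f"t{i}": np.sqrt(0.5) * g + np.sqrt(0.5) * rng.standard_normal(n)
            for i in range(4)
        }
        df = pd.DataFrame(comps)
        s = composite_score(df)
        # brute-force oracle: largest-eigenvalue vector of the empirical
        # correlation matrix applied to the standardised data
        z = (df - df.mean()) / df.std(ddof=1)
        corr = np.corrcoef(z.to_numpy(), rowvar=False)
        w, v = np.linalg.eig(corr)
        lead = np.real(v[:, np.argmax(np.real(w))])
        oracle = z.to_numpy() @ lead
        oracle *= np.sign(np.corrcoef(oracle, z.iloc[:, 0])[0, 1])
        oracle = (oracle - oracle.mean()) / oracle.std(ddof=1)
        np.testing.assert_allclose(s.to_numpy(), oracle, atol=1e-8)
        # equicorrelated structure: loadings near-uniform
        assert np.corrcoef(s, z.sum(axis=1))[0, 1] > 0.999

    def test_missing_component_gives_missing_score(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan], "b": [0.5, 1.5, 2.0],
                           "c": [1.0, 0.0, 1.0]})
        s = composite_score(df)
        assert np.isnan(s.iloc[2])

    def test_constant_component_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.standard_normal(100),
                           "b": rng.standard_normal(100),
                           "k": np.ones(100)})
        with pytest.warns(RuntimeWarning, match="constant"):
            s = composite_score(df)
        assert s.notna().all()

    def test_fewer_than_two_components_rejected(self):
        with pytest.raises(ConfigError):
            composite_score(pd.DataFrame({"a": [1.0, 2.0], "k": [1.0, 1.0]}))


COX_META = {
    "time": VariableMeta("time", 1, "continuous"),
    "event": VariableMeta("event", 1, "binary"),
    "x": VariableMeta("x", 1, "binary"),
}


def brute_force_cox_beta(time, event, x):
    """Direct maximisation of the (untied, Breslow=exact) partial likelihood."""
    order = np.argsort(time)
    t, e, xv = time[order], event[order], x[order]

    def negloglik(beta):
        ll = 0.0
        for i in range(len(t)):
            if e[i] == 1:
                risk = xv[i:]  # all with time >= t[i]
                ll += beta * xv[i] - np.log(np.sum(np.exp(beta * risk)))
        return -ll

    res = minimize(lambda b: negloglik(b[0]), [0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    return res.x[0]


class TestCox:
    def test_six_untied_observations_match_brute_force(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        res = fit_cox(df, "time", "event", ["x"], COX_META)
        beta_bf = brute_force_cox_beta(time, event, x)
        assert res.loc["x", "beta"] == pytest.approx(beta_bf, abs=1e-6)

    def test_null_two_group_hr_near_one(self):
        rng = np.random.default_rng(5)
        n = 3000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0, n)
        df = pd.DataFrame({"time": t, "event": np.ones(n), "x": x})
        res = fit_cox(df, "time", "event", ["x"], COX_META)
        assert res.loc["x", "hr_lo"] < 1.0 < res.loc["x", "hr_hi"]
        assert res.loc["x", "hr"] == pytest.approx(1.0, abs=0.15)

    def test_simulated_hazard_ratio_recovered(self):
        rng = np.random.default_rng(6)
        n = 10000
        x = (rng.random(n) < 0.5).astype(float)
        lam = 0.1 * np.exp(np.log(0.5) * x)
        t = rng.exponential(1.0 / lam)
        cens = np.quantile(t, 0.10)  # ~10% events
        df = pd.DataFrame({
            "time": np.minimum(t, cens), "event": (t <= cens).astype(float),
            "x": x,
        })
        res = fit_cox(df, "time", "event", ["x"], COX_META)
        half_width = res.loc["x", "hr_hi"] - res.loc["x", "hr"]
        assert abs(res.loc["x", "hr"] - 0.5) < half_width

    def test_left_truncation_restricts_risk_set(self):
        rng = np.random.default_rng(7)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(5.0, n)
        df = pd.DataFrame({"time": t, "event": np.ones(n), "x": x})
        res = fit_cox(df, "time", "event", ["x"], COX_META, entry_time=2.0)
        assert res.loc["x", "se"] > 0

    def test_eventless_level_dropped_with_warning(self):
        meta = dict(COX_META)
        meta["g"] = VariableMeta("g", 1, "categorical",
                                 category_labels=("a", "b", "c"))
        rng = np.random.default_rng(8)
        n = 300
        g = rng.choice(np.array(["a", "b", "c"], dtype=object), n)
        event = np.where(g == "c", 0.0, 1.0)
        df = pd.DataFrame({"time": rng.exponential(1, n), "event": event, "g": g})
        with pytest.warns(RuntimeWarning, match="no events"):
            res = fit_cox(df, "time", "event", ["g"], meta)
        assert "g[c]" not in res.index


@pytest.fixture(scope="module")
def zero_nr_cohort():
    cfg = SimConfig(
        n_members=1500, n_sweeps=3, seed=17, mechanism="MCAR",
        nonresponse_rate=0.0, sweep1_nonresponse=False,
        item_missing_rate=0.0, emigration_rate=0.01,
        mortality=MortalityModel(baseline_hazard=0.005), n_noise_vars=0,
    )
    cohort, _ = simulate(cfg)
    return cohort


class TestTravelBack:
    def test_zero_nonresponse_collapses_all_arms(self, zero_nr_cohort):
        rep = travel_back(
            zero_nr_cohort, Estimand(kind="mean", variable="copying_designs"),
            3, ["father_social_class"], MIConfig(m=3, seed=0),
        )
        r = rep.rows[0]
        assert r["truth"] == r["cc"] == r["mi"]
        assert r["bias_cc"] == r["bias_mi"] == 0.0

    def test_category_percentages_sum_to_100_per_arm(self):
        cfg = SimConfig(n_members=3000, n_sweeps=3, seed=18, mechanism="MAR",
                        nonresponse_rate=(0.02, 0.1, 0.4))
        cohort, _ = simulate(cfg)
        sums = {"truth": 0.0, "cc": 0.0, "mi": 0.0}
        for lv in cohort.meta["country"].category_labels:
            rep = travel_back(
                cohort,
                Estimand(kind="category_percentage", variable="country",
                         category=lv),
                3, ["father_social_class", "sex"],
                MIConfig(m=3, n_iterations=2, seed=7),
            )
            for k in sums:
                sums[k] += rep.rows[0][k]
        for k, total in sums.items():
            assert total == pytest.approx(100.0, abs=1e-6), k

    def test_report_deterministic_given_seed(self, zero_nr_cohort):
        est = Estimand(kind="mean", variable="copying_designs")
        a = travel_back(zero_nr_cohort, est, 3, ["sex"], MIConfig(m=3, seed=3))
        b = travel_back(zero_nr_cohort, est, 3, ["sex"], MIConfig(m=3, seed=3))
        assert a.rows == b.rows

    def test_missing_estimand_variable_rejected(self, zero_nr_cohort):
        with pytest.raises(ConfigError, match="unavailable"):
            travel_back(zero_nr_cohort,
                        Estimand(kind="mean", variable="nope"), 3, [],
                        MIConfig(m=2, seed=0))
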