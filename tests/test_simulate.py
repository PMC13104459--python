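"""Simulator contracts: determinism, mechanism semantics, ground truth."""

import io
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cohortmi import (
    ExtraVar,
    MortalityModel,
    SimConfig,
    derive_nonresponse,
    mechanism_probability,
    participation_summary,
    simulate,
    write_cohort,
)
from cohortmi.errors import ConfigError


def flat_config(**kw):
    base = dict(
        n_members=5000, n_sweeps=2, seed=0, mechanism="MCAR",
        nonresponse_rate=0.3, sweep1_nonresponse=False,
        prior_nonresponse_effect=0.0, item_missing_rate=0.0,
        emigration_rate=0.0, mortality=MortalityModel(baseline_hazard=0.0),
        n_noise_vars=0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_byte_identical_repeat(self, tmp_path):
        cfg = SimConfig(n_members=500, seed=9)
        for d in ("a", "b"):
            (tmp_path / d).mkdir()
            cohort, _ = simulate(cfg)
            write_cohort(cohort, tmp_path / d / "c.csv", tmp_path / d / "m.csv")
        assert (tmp_path / "a/c.csv").read_bytes() == (tmp_path / "b/c.csv").read_bytes()
        assert (tmp_path / "a/m.csv").read_bytes() == (tmp_path / "b/m.csv").read_bytes()


class TestMCAR:
    def test_marginal_rate_and_independence(self):
        cohort, _ = simulate(flat_config())
        frame, ind = derive_nonresponse(cohort, 2)
        rate = frame.nonresponse_rate
        se = np.sqrt(0.3 * 0.7 / frame.eligible_n)
        assert abs(rate - 0.3) < 3 * se
        # no covariate should associate with the indicator after Bonferroni
        num_cols = [
            c for c in cohort.values.columns
            if cohort.meta[c].var_type != "categorical"
            and c not in ("surv_time", "surv_event")
        ]
        pvals = []
        for c in num_cols:
            x = cohort.values[c]
            ok = x.notna() & ind.notna()
            if ok.sum() < 50 or x[ok].std() == 0:
                continue
            pvals.append(stats.pearsonr(x[ok], ind[ok]).pvalue)
        assert min(pvals) > 0.01 / len(pvals)

    def test_complete_case_baseline_mean_unbiased(self):
        # replicated MCAR cohorts: average complete-case bias ~ 0
        biases = []
        for seed in range(200):
            cohort, _ = simulate(flat_config(n_members=2000, seed=seed))
            resp = cohort.status[2] == "R"
            x = cohort.values["copying_designs"]
            biases.append(float(x[resp].mean() - x.mean()))
        mean_bias = np.mean(biases)
        se = np.std(biases, ddof=1) / np.sqrt(len(biases))
        assert abs(mean_bias) < 3 * se + 1e-3


class TestMAR:
    def test_group_proportion_oracle_recovers_risk_ratio(self):
        cfg = flat_config(
            n_members=20000, mechanism="MAR",
            true_predictors=(("father_social_class", 0.2),),
        )
        cohort, _ = simulate(cfg)
        _, ind = derive_nonresponse(cohort, 2)
        cls = cohort.values["father_social_class"]
        # oracle: direct non-response proportion per adjacent class pair
        log_ratios = []
        for k in range(5):
            p1 = ind[cls == k + 1].mean()
            p0 = ind[cls == k].mean()
            log_ratios.append(np.log(p1 / p0))
        assert np.mean(log_ratios) == pytest.approx(0.2, abs=0.05)

    def test_complete_case_bias_direction(self):
        # attrition driven by an observed score biases correlated variables
        cfg = flat_config(
            n_members=20000, n_sweeps=3,
            nonresponse_rate=(0.0, 0.0, 0.4), mechanism="MAR",
            true_predictors=(("copying_designs", 0.5),),
        )
        cohort, _ = simulate(cfg)
        resp = cohort.status[3] == "R"
        for var in ("picture_vocab", "figure_drawing"):
            x = cohort.values[var]  # fully observed before the target sweep
            assert x[resp].mean() < x.mean()  # positive effect on non-response


class TestMNAR:
    def test_nonrespondents_have_higher_true_values(self):
        cfg = flat_config(
            mechanism="MNAR", mnar_variable="copying_designs", mnar_effect=0.6,
            true_predictors=(),
        )
        cohort, truth = simulate(cfg)
        _, ind = derive_nonresponse(cohort, 2)
        x = truth.complete["copying_designs"]
        assert x[ind == 1].mean() > x[ind == 0].mean() + 0.1


class TestMechanismProbability:
    def test_zero_effects_give_intercept_rate(self):
        cfg = flat_config(mechanism="MAR", true_predictors=())
        p = mechanism_probability({"sex": 1.0}, 2, cfg)
        assert p == pytest.approx(0.3)

    def test_doubling_effect_widens_gap(self):
        lo = flat_config(mechanism="MAR", true_predictors=(("sex", 0.2),))
        hi = flat_config(mechanism="MAR", true_predictors=(("sex", 0.4),))
        gap_lo = mechanism_probability({"sex": 1.0}, 2, lo) - mechanism_probability(
            {"sex": 0.0}, 2, lo
        )
        gap_hi = mechanism_probability({"sex": 1.0}, 2, hi) - mechanism_probability(
            {"sex": 0.0}, 2, hi
        )
        assert gap_hi > gap_lo > 0

    def test_cap_warns(self):
        cfg = flat_config(mechanism="MAR", true_predictors=(("x", 5.0),),
                          extra_vars=(ExtraVar("x", 1, "continuous"),))
        with pytest.warns(RuntimeWarning, match="capped"):
            p = mechanism_probability({"x": 3.0}, 2, cfg)
        assert p == 0.99

    def test_ground_truth_reproduces_generated_probabilities(self):
        cfg = SimConfig(n_members=1000, n_sweeps=4, seed=3, mechanism="MAR")
        cohort, truth = simulate(cfg)
        for t in (2, 3, 4):
            eta = truth.intercepts[t] + truth.linear_contrib[t]
            p = np.minimum(np.exp(eta), 0.99)
            for mid in cohort.member_ids[:20]:
                assert truth.nonresponse_probability(mid, t) == pytest.approx(
                    p[mid]
                )


class TestStructure:
    def test_eligible_counts_nonincreasing_with_attrition(self, sim_cohort):
        cohort, _ = sim_cohort
        elig = participation_summary(cohort)["eligible"].to_numpy()
        assert (np.diff(elig) <= 0).all()

    def test_routed_child_observed_only_with_parent(self):
        cfg = SimConfig(n_members=2000, n_sweeps=2, seed=4, mechanism="MCAR",
                        nonresponse_rate=0.0, sweep1_nonresponse=False,
                        item_missing_rate=0.0, emigration_rate=0.0,
                        mortality=MortalityModel(baseline_hazard=0.0),
                        n_noise_vars=20, routed_fraction=0.5,
                        rare_binary_fraction=0.0)
        cohort, _ = simulate(cfg)
        pairs = [(p, p.replace("parent", "child"))
                 for p in cohort.values.columns if "route_parent" in p]
        assert pairs
        for parent, child in pairs:
            pv, cv = cohort.values[parent], cohort.values[child]
            assert cv[pv == 0].isna().all()
            assert cv[pv == 1].notna().all()

    def test_unknown_true_predictor_rejected(self):
        with pytest.raises(ConfigError, match="ungenerated"):
            simulate(flat_config(mechanism="MAR",
                                 true_predictors=(("no_such_var", 0.3),)))

    def test_invalid_mechanism_rejected(self):
        with pytest.raises(ConfigError, match="mechanism"):
            SimConfig(mechanism="MARS")
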