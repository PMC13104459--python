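"""Synthetic multi-sweep birth cohorts with known non-response mechanisms.

The generator emulates the structural features of a 1970s British birth
cohort followed over ~10 sweeps: socio-economic baseline covariates (sex,
six-level paternal social class, parity, country, parental marital status,
father's education-age band), four correlated early-childhood test scores
feeding a cognitive composite, later-sweep behavioural variables (household
moves, an election-voting indicator), deaths and emigration as competing
absorbing states, a continuous survival time whose hazard depends on
paternal social class, plus configurable pools of null "noise" variables,
routed child questions, and rare binaries.

Non-response at each sweep is drawn on the log-risk scale so that generation
and analysis share the risk-ratio parameterisation:

    P(non-response | x) = min(exp(eta), 0.99),
    eta = intercept_t + sum_j beta_j * x_j + beta_prior * prior_incomplete
          [+ beta_mnar * x_mnar  under MNAR]

Under MCAR all betas are zero; under MAR the contributions come only from
values that are actually observed (collected at a sweep the member responded
to); under MNAR the designated variable contributes through its true,
possibly unobserved, current value.  The per-sweep intercept is calibrated
against the realised covariate distribution (a log-mean-exp correction) so
the marginal non-response rate matches the configured target.

Every generated probability can be reproduced exactly from the returned
:class:`GroundTruth`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CohortTable,
    DEAD,
    EMIGRATED,
    NONRESPONDENT,
    RESPONDENT,
    VariableMeta,
)
from .errors import ConfigError

PROB_CAP = 0.99

CLASS_LABELS = (
    "single_unskilled_other",
    "partly_skilled",
    "manual",
    "non_manual",
    "managerial_technical",
    "professional",
)
COUNTRY_LABELS = ("england", "wales", "scotland", "other")
MARITAL_LABELS = ("single", "married", "sep_div_wid")
EDU_LABELS = ("le15", "16_18", "ge19")
TEST_SCORES = ("copying_designs", "picture_vocab", "figure_drawing", "profile_test")

# Marginal non-response targets per sweep, shaped like the published
# participation profile (low in the parent-interview era, ~40-50% in the
# adult sweeps).
DEFAULT_NR_RATES = (0.05, 0.25, 0.15, 0.33, 0.48, 0.34, 0.42, 0.47, 0.41, 0.48)

# Default non-response effects (log risk ratios per unit / per level) of
# realistic magnitude: risk ratios roughly 0.7-1.5 across a variable's range.
DEFAULT_TRUE_PREDICTORS: tuple[tuple[str, object], ...] = (
    ("father_social_class", -0.045),
    ("sex", -0.15),
    ("parity", 0.035),
    ("household_moves", 0.04),
    ("copying_designs", -0.03),
    ("voting_no", 0.10),
    ("country", {"england": 0.0, "wales": -0.25, "scotland": -0.08, "other": 0.25}),
)


@dataclass(frozen=True)
class ExtraVar:
    """An additional generated variable (used for calibration experiments)."""

    name: str
    origin_sweep: int = 1
    kind: str = "continuous"  # or "binary"
    prevalence: float = 0.5   # binary only
    sd: float = 1.0           # continuous only

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ConfigError(f"extra variable {self.name}: unknown kind {self.kind}")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError(f"extra variable {self.name}: prevalence out of (0,1)")


@dataclass(frozen=True)
class MortalityModel:
    """Exponential mortality with a log-linear paternal-class gradient.

    ``baseline_hazard`` is the per-sweep-interval hazard in the reference
    (most disadvantaged) class; each step up the class scale multiplies the
    hazard by ``exp(log_hr_per_level)``.  The death clock starts after the
    birth sweep, so nobody is dead at sweep 1.
    """

    baseline_hazard: float = 0.0065
    exposure: str = "father_social_class"
    log_hr_per_level: float = -0.12

    def __post_init__(self) -> None:
        if self.baseline_hazard < 0:
            raise ConfigError("baseline_hazard must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    n_members: int = 5000
    n_sweeps: int = 10
    seed: int = 0
    mechanism: str = "MAR"  # MCAR, MAR, MNAR
    nonresponse_rate: tuple[float, ...] | float = DEFAULT_NR_RATES
    true_predictors: tuple[tuple[str, object], ...] = DEFAULT_TRUE_PREDICTORS
    prior_nonresponse_effect: float = 0.6
    mnar_variable: str | None = None
    mnar_effect: float = 0.0
    mortality: MortalityModel = field(default_factory=MortalityModel)
    emigration_rate: float = 0.003
    item_missing_rate: float = 0.03
    n_noise_vars: int = 20
    routed_fraction: float = 0.1
    rare_binary_fraction: float = 0.1
    extra_vars: tuple[ExtraVar, ...] = ()
    sweep1_nonresponse: bool = True

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR", "MNAR"):
            raise ConfigError(f"mechanism: unknown mechanism {self.mechanism!r}")
        for name in ("emigration_rate", "item_missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        for r in self.rates():
            if not 0.0 <= r <= 1.0:
                raise ConfigError(f"nonresponse_rate entries must be in [0,1], got {r}")
        if self.n_noise_vars < 0:
            raise ConfigError("n_noise_vars must be >= 0")
        for name, eff in self.true_predictors:
            vals = eff.values() if isinstance(eff, Mapping) else [eff]
            if not all(np.isfinite(list(vals))):
                raise ConfigError(f"effect for {name} must be finite")
        if self.mechanism == "MNAR" and not self.mnar_variable:
            raise ConfigError("mnar_variable: required when mechanism is MNAR")

    def rates(self) -> tuple[float, ...]:
        if isinstance(self.nonresponse_rate, (int, float)):
            return (float(self.nonresponse_rate),) * self.n_sweeps
        r = tuple(self.nonresponse_rate)
        if len(r) < self.n_sweeps:
            r = r + (r[-1],) * (self.n_sweeps - len(r))
        return r[: self.n_sweeps]


@dataclass
class GroundTruth:
    """Everything needed to reproduce the generating process exactly."""

    config: SimConfig
    true_predictor_names: tuple[str, ...]
    intercepts: dict[int, float]
    complete: pd.DataFrame          # pre-masking values, incl. structural NaN
    observed_at_origin: pd.DataFrame  # bool: value collected (member responded)
    linear_contrib: pd.DataFrame    # per member x sweep covariate contribution
    ability: pd.Series

    def nonresponse_probability(self, member_id, sweep: int) -> float:
        """Exact probability of non-response used when generating ``sweep``."""
        eta = self.intercepts[sweep] + float(
            self.linear_contrib.loc[member_id, sweep]
        )
        return min(float(np.exp(eta)), PROB_CAP)

    def to_json(self) -> str:
        d = {
            "config": _config_to_dict(self.config),
            "true_predictor_names": list(self.true_predictor_names),
            "intercepts": {str(k): v for k, v in self.intercepts.items()},
        }
        return json.dumps(d, indent=2, sort_keys=True)


def _config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    d["true_predictors"] = [
        [n, dict(e) if isinstance(e, Mapping) else e]
        for n, e in config.true_predictors
    ]
    return d


def mechanism_probability(
    covariates: Mapping[str, object],
    sweep: int,
    config: SimConfig,
    intercept: float | None = None,
    prior_incomplete: float = 0.0,
) -> float:
    """Probability of non-response for one member at ``sweep``.

    With ``intercept=None`` the uncalibrated intercept ``log(rate_t)`` is
    used, so with all effects zero the returned probability equals the
    configured marginal rate.  Under MAR the contribution of a covariate that
    is missing from ``covariates`` (i.e. unobserved) is zero; under MNAR the
    designated variable always contributes through its supplied true value.
    Probabilities above the cap are truncated with a warning.
    """
    if intercept is None:
        intercept = float(np.log(config.rates()[sweep - 1]))
    eta = intercept + config.prior_nonresponse_effect * prior_incomplete
    if config.mechanism != "MCAR":
        for name, eff in config.true_predictors:
            val = covariates.get(name)
            if val is None or (isinstance(val, float) and np.isnan(val)):
                continue
            if isinstance(eff, Mapping):
                eta += float(eff.get(val, 0.0))
            else:
                eta += float(eff) * float(val)
    if config.mechanism == "MNAR" and config.mnar_variable:
        val = covariates.get(config.mnar_variable)
        if val is not None and np.isfinite(float(val)):
            eta += config.mnar_effect * float(val)
    p = float(np.exp(eta))
    if p > PROB_CAP:
        warnings.warn(
            f"non-response probability {p:.3f} capped at {PROB_CAP}",
            RuntimeWarning,
            stacklevel=2,
        )
        p = PROB_CAP
    return p


def _gen_builtin(
    rng: np.random.Generator, n: int, S: int
) -> tuple[dict[str, np.ndarray], dict[str, VariableMeta], pd.Series]:
    """Built-in cohort variables; returns values, meta, latent ability."""
    vals: dict[str, np.ndarray] = {}
    meta: dict[str, VariableMeta] = {}

    def add(name, arr, sweep, var_type, labels=None):
        vals[name] = arr
        meta[name] = VariableMeta(
            name=name,
            origin_sweep=sweep,
            var_type=var_type,
            category_labels=tuple(labels) if labels else None,
        )

    add("sex", (rng.random(n) < 0.49).astype(float), 1, "binary")
    class_p = np.array([0.10, 0.16, 0.44, 0.12, 0.13, 0.05])
    cls = rng.choice(6, size=n, p=class_p).astype(float)
    add("father_social_class", cls, 1, "ordinal", CLASS_LABELS)
    parity_p = np.array([0.37, 0.35, 0.16, 0.07, 0.05])
    add("parity", rng.choice(5, size=n, p=parity_p).astype(float), 1, "ordinal",
        ("0", "1", "2", "3", "4plus"))
    country_p = np.array([0.83, 0.05, 0.09, 0.03])
    add("country", rng.choice(np.array(COUNTRY_LABELS, dtype=object), size=n,
                              p=country_p), 1, "categorical", COUNTRY_LABELS)
    add("marital_status", rng.choice(np.array(MARITAL_LABELS, dtype=object),
                                     size=n, p=[0.06, 0.92, 0.02]),
        1, "categorical", MARITAL_LABELS)
    add("father_edu_age", rng.choice(3, size=n, p=[0.66, 0.24, 0.10]).astype(float),
        1, "ordinal", EDU_LABELS)

    z_class = (cls - cls.mean()) / max(cls.std(), 1e-9)
    ability = 0.25 * z_class + np.sqrt(1 - 0.25**2) * rng.standard_normal(n)
    if S >= 2:
        for t in TEST_SCORES:
            add(t, np.sqrt(0.5) * ability + np.sqrt(0.5) * rng.standard_normal(n),
                2, "continuous")
        lam = np.exp(0.0 - 0.08 * z_class)
        add("household_moves", rng.poisson(lam).astype(float), 2, "continuous")
    if S >= 3:
        add("bas_score", 0.6 * ability + 0.8 * rng.standard_normal(n), 3,
            "continuous")
    if S >= 5:
        p_no = np.clip(0.30 - 0.05 * z_class, 0.01, 0.99)
        add("voting_no", (rng.random(n) < p_no).astype(float), 5, "binary")
    return vals, meta, pd.Series(ability)


def _gen_pool(
    rng: np.random.Generator, n: int, config: SimConfig
) -> tuple[dict[str, np.ndarray], dict[str, VariableMeta]]:
    """Noise variables, routed pairs and rare binaries."""
    vals: dict[str, np.ndarray] = {}
    meta: dict[str, VariableMeta] = {}
    S = config.n_sweeps
    sweeps = list(range(1, max(S, 2)))  # origin sweeps 1..S-1
    k = config.n_noise_vars
    n_rare = int(np.floor(config.rare_binary_fraction * k))
    n_routed = int(np.floor(config.routed_fraction * k / 2.0))  # pairs use 2 slots
    n_plain = k - n_rare - 2 * n_routed
    i = 0

    def sweep_of(j):
        return sweeps[j % len(sweeps)]

    for j in range(n_plain):
        s = sweep_of(i)
        if j % 2 == 0:
            name = f"noise_c{j}_s{s}"
            vals[name] = rng.standard_normal(n)
            meta[name] = VariableMeta(name, s, "continuous")
        else:
            name = f"noise_b{j}_s{s}"
            vals[name] = (rng.random(n) < 0.5).astype(float)
            meta[name] = VariableMeta(name, s, "binary")
        i += 1
    for j in range(n_rare):
        s = sweep_of(i)
        prev = rng.uniform(0.001, 0.03)
        name = f"rare_b{j}_s{s}"
        vals[name] = (rng.random(n) < prev).astype(float)
        meta[name] = VariableMeta(name, s, "binary")
        i += 1
    for j in range(n_routed):
        s = sweep_of(i)
        parent = f"route_parent{j}_s{s}"
        child = f"route_child{j}_s{s}"
        pv = (rng.random(n) < 0.5).astype(float)
        cv = rng.standard_normal(n)
        cv[pv == 0] = np.nan  # structural: question not asked
        vals[parent] = pv
        vals[child] = cv
        meta[parent] = VariableMeta(parent, s, "binary")
        meta[child] = VariableMeta(child, s, "continuous", routed=True)
        i += 1
    for ev in config.extra_vars:
        if ev.kind == "binary":
            vals[ev.name] = (rng.random(n) < ev.prevalence).astype(float)
        else:
            vals[ev.name] = ev.sd * rng.standard_normal(n)
        meta[ev.name] = VariableMeta(ev.name, ev.origin_sweep, ev.kind
                                     if ev.kind == "binary" else "continuous")
    return vals, meta


def simulate(config: SimConfig) -> tuple[CohortTable, GroundTruth]:
    """Generate a cohort and its ground truth from ``config``.

    Deterministic given the config (including its seed): repeated calls
    return identical output.
    """
    rng = np.random.default_rng(config.seed)
    n, S = config.n_members, config.n_sweeps
    vals, meta, ability = _gen_builtin(rng, n, S)
    pool_vals, pool_meta = _gen_pool(rng, n, config)
    vals.update(pool_vals)
    meta.update(pool_meta)

    builtin_known = set(TEST_SCORES) | {
        "sex", "father_social_class", "parity", "country", "marital_status",
        "father_edu_age", "household_moves", "bas_score", "voting_no",
    }
    for name, eff in config.true_predictors:
        if name not in vals and config.mechanism != "MCAR":
            # built-ins may be absent in short cohorts; anything else is a typo
            if name in builtin_known:
                continue
            raise ConfigError(
                f"true predictor {name!r} references an ungenerated variable"
            )

    complete = pd.DataFrame(vals, index=pd.RangeIndex(n, name="member_id"))

    # survival: death clock starts after the birth sweep
    mm = config.mortality
    cls = complete[mm.exposure].to_numpy(dtype=float)
    rate = mm.baseline_hazard * np.exp(mm.log_hr_per_level * cls)
    T = 1.0 + rng.exponential(1.0 / np.maximum(rate, 1e-12))
    surv_time = np.minimum(T, float(S))
    surv_event = (T <= S).astype(float)
    complete["surv_time"] = surv_time
    complete["surv_event"] = surv_event
    meta["surv_time"] = VariableMeta("surv_time", S, "continuous")
    meta["surv_event"] = VariableMeta("surv_event", S, "binary")

    emig_u = rng.random((n, S))
    nr_u = rng.random((n, S))

    status = np.full((n, S), RESPONDENT, dtype=object)
    rates = config.rates()
    intercepts: dict[int, float] = {}
    contrib = pd.DataFrame(0.0, index=complete.index, columns=range(1, S + 1))

    # sweep 1: optional MCAR-style birth-sweep non-response
    if config.sweep1_nonresponse and rates[0] > 0:
        intercepts[1] = float(np.log(max(rates[0], 1e-12)))
        status[nr_u[:, 0] < rates[0], 0] = NONRESPONDENT

    responded = status[:, 0] == RESPONDENT  # responded at each var's origin sweep
    observed = pd.DataFrame(False, index=complete.index, columns=complete.columns)

    # record observation (collection) of sweep-1 variables
    for name, m in meta.items():
        if m.origin_sweep == 1:
            observed[name] = responded & complete[name].notna()

    dead = np.zeros(n, dtype=bool)
    emigrated = np.zeros(n, dtype=bool)
    ever_nonresp = status[:, 0] == NONRESPONDENT

    for t in range(2, S + 1):
        # deaths after emigration are unobserved: emigrants stay emigrated
        dead |= (~emigrated) & (T < t)
        new_emig = (~dead) & (~emigrated) & (emig_u[:, t - 1] < config.emigration_rate)
        emigrated |= new_emig
        status[dead, t - 1] = DEAD
        status[emigrated & ~dead, t - 1] = EMIGRATED
        eligible = ~dead & ~emigrated

        # linear contribution from observed true predictors + MNAR term
        eta_c = np.zeros(n)
        if config.mechanism != "MCAR":
            for name, eff in config.true_predictors:
                if name not in complete.columns:
                    continue
                if meta[name].origin_sweep >= t:
                    continue  # not yet collected: cannot drive response at t
                obs_mask = observed[name].to_numpy()
                x = complete[name]
                if isinstance(eff, Mapping):
                    c = x.map(lambda v: float(eff.get(v, 0.0))).to_numpy(dtype=float)
                else:
                    c = float(eff) * pd.to_numeric(x).fillna(0.0).to_numpy()
                eta_c += np.where(obs_mask, np.nan_to_num(c), 0.0)
        if config.mechanism == "MNAR" and config.mnar_variable:
            xm = pd.to_numeric(complete[config.mnar_variable], errors="coerce")
            xm = xm.fillna(xm.mean()).to_numpy()
            eta_c += config.mnar_effect * (xm - xm.mean())
        eta_c += config.prior_nonresponse_effect * ever_nonresp.astype(float)
        contrib[t] = eta_c

        # calibrate the intercept so the marginal rate matches the target
        target = rates[t - 1]
        if target <= 0:
            intercepts[t] = -np.inf
            p = np.zeros(n)
        else:
            adj = float(np.log(np.mean(np.exp(eta_c[eligible])))) if eligible.any() else 0.0
            intercepts[t] = float(np.log(target)) - adj
            p = np.minimum(np.exp(intercepts[t] + eta_c), PROB_CAP)
        nonresp = eligible & (nr_u[:, t - 1] < p)
        status[nonresp, t - 1] = NONRESPONDENT
        ever_nonresp |= nonresp

        resp_t = eligible & ~nonresp
        for name, m in meta.items():
            if m.origin_sweep == t:
                observed[name] = resp_t & complete[name].notna()

    # observed values: mask wave non-response, then sporadic item missingness
    values = complete.copy()
    item_u = rng.random(values.shape)
    obs_np = observed.to_numpy()
    keep = obs_np & (item_u >= config.item_missing_rate)
    # survival is registry data: observed for everyone
    for name in ("surv_time", "surv_event"):
        j = values.columns.get_loc(name)
        keep[:, j] = True
    arr = values.to_numpy(dtype=object)
    arr[~keep] = np.nan
    values = pd.DataFrame(arr, index=values.index, columns=values.columns)
    for name, m in meta.items():
        if m.var_type in ("continuous", "binary", "ordinal"):
            values[name] = pd.to_numeric(values[name], errors="coerce")

    status_df = pd.DataFrame(
        status, index=complete.index, columns=range(1, S + 1)
    )
    cohort = CohortTable(values, status_df, meta)
    truth = GroundTruth(
        config=config,
        true_predictor_names=tuple(
            n_ for n_, _ in config.true_predictors if n_ in complete.columns
        )
        if config.mechanism != "MCAR"
        else (),
        intercepts=intercepts,
        complete=complete,
        observed_at_origin=observed,
        linear_contrib=contrib,
        ability=ability,
    )
    return cohort, truth
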