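"""Multiple imputation by chained equations, Rubin pooling, delta adjustment.

The engine imputes mixed-type data (continuous, binary, categorical,
ordinal) by iterating univariate conditional models over the incomplete
variables in order of increasing missingness.  Conditional methods:

* continuous — predictive mean matching (default; imputations are observed
  donor values, robust to non-normality) or a proper Bayesian normal-linear
  draw (``norm``; required for exact delta-shift algebra),
* binary — logistic regression on a bootstrap resample of the observed rows
  (the bootstrap propagates parameter uncertainty), draws from the fitted
  probabilities, with a ridge-stabilised fallback under perfect prediction,
* categorical — multinomial logistic, bootstrap + probability draws,
* ordinal — predictive mean matching on the numeric codes (donor values are
  observed codes, so imputations are always valid levels).

Fully observed variables — in particular the non-response indicator, which
is appended to every imputation model in this workflow — act as predictors
only and are never altered; observed cells of incomplete variables are never
altered either.

Delta adjustment shifts the *imputed* (never observed) values of a target
variable by a constant, representing a missing-not-at-random departure;
``calibrate_delta`` root-finds the shift that makes the pooled mean match an
external benchmark, optionally per stratum.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .cohort import VariableMeta
from .errors import ConfigError, ConvergenceError
from .poisson import Z975

logger = logging.getLogger(__name__)

DEFAULT_METHODS = {
    "continuous": "pmm",
    "binary": "logistic",
    "categorical": "multinomial",
    "ordinal": "pmm",
}


@dataclass(frozen=True)
class MIConfig:
    m: int = 20
    n_iterations: int = 10
    seed: int = 0
    methods: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_METHODS))
    pmm_donors: int = 5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ConfigError(f"m must be >= 2, got {self.m}")
        if self.n_iterations < 1:
            raise ConfigError(f"n_iterations must be >= 1, got {self.n_iterations}")
        if self.pmm_donors < 1:
            raise ConfigError(f"pmm_donors must be >= 1, got {self.pmm_donors}")

    def method_for(self, var_type: str) -> str:
        return self.methods.get(var_type, DEFAULT_METHODS[var_type])


@dataclass(frozen=True)
class PooledEstimate:
    """Rubin's-rules combination of per-imputation estimates."""

    point: float
    W: float           # mean within-imputation variance
    B: float           # between-imputation variance
    m: int

    @property
    def T(self) -> float:
        return self.W + (1.0 + 1.0 / self.m) * self.B

    @property
    def se(self) -> float:
        return float(np.sqrt(self.T))

    @property
    def df(self) -> float:
        if self.B <= 0:
            return float("inf")
        r = (1.0 + 1.0 / self.m) * self.B / self.W if self.W > 0 else np.inf
        with np.errstate(over="ignore"):
            # overflows to inf for vanishing B/W, which is the right limit
            return float((self.m - 1) * np.square(np.float64(1.0 + 1.0 / r)))

    @property
    def p(self) -> float:
        if self.se == 0:
            return 0.0 if self.point != 0 else 1.0
        t = abs(self.point) / self.se
        df = self.df
        if np.isinf(df):
            return float(2.0 * stats.norm.sf(t))
        return float(2.0 * stats.t.sf(t, df))

    @property
    def ci95(self) -> tuple[float, float]:
        df = self.df
        q = Z975 if np.isinf(df) else float(stats.t.ppf(0.975, df))
        return (self.point - q * self.se, self.point + q * self.se)


def pool(
    points: Sequence[float], variances: Sequence[float]
) -> PooledEstimate:
    """Pool per-imputation (point, variance) pairs by Rubin's rules.

    Ratio-scale quantities (risk or hazard ratios) must be supplied on the
    log scale and exponentiated after pooling.
    """
    pts = np.asarray(points, dtype=float)
    vs = np.asarray(variances, dtype=float)
    if pts.shape != vs.shape:
        raise ValueError("points and variances must have the same length")
    m = len(pts)
    if m < 2:
        raise ValueError("pooling requires at least two imputations")
    point = float(pts.mean())
    W = float(vs.mean())
    # exactly identical estimates must give exactly zero between variance
    B = 0.0 if np.ptp(pts) == 0 else float(pts.var(ddof=1))
    return PooledEstimate(point=point, W=W, B=B, m=m)


@dataclass(frozen=True)
class DeltaConfig:
    target_variable: str
    benchmark: float | Mapping[str, float] | None = None
    bracket: tuple[float, float] = (-10.0, 10.0)
    stratified: bool = False
    stratum_variable: str | None = None
    tol: float = 1e-3
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.stratified and not self.stratum_variable:
            raise ConfigError("stratum_variable: required when stratified")


# ---------------------------------------------------------------------------
# chained-equations core


def _encode_predictors(
    df: pd.DataFrame,
    meta: Mapping[str, VariableMeta],
    exclude: str,
) -> np.ndarray:
    """Numeric predictor matrix from all columns but ``exclude``."""
    cols = [np.ones(len(df))]
    for name in df.columns:
        if name == exclude:
            continue
        m = meta[name]
        s = df[name]
        if m.var_type == "categorical":
            levels = list(m.category_labels or pd.unique(s.dropna()))
            for lv in levels[1:]:
                cols.append((s == lv).to_numpy(dtype=float))
        else:
            cols.append(pd.to_numeric(s).to_numpy(dtype=float))
    return np.column_stack(cols)


def _draw_norm(
    rng: np.random.Generator, X_obs, y_obs, X_mis
) -> np.ndarray:
    """Proper Bayesian normal-linear imputation draw."""
    n, k = X_obs.shape
    beta_hat, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - k, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    XtX = X_obs.T @ X_obs
    XtX_inv = np.linalg.pinv(XtX)
    L = np.linalg.cholesky(
        XtX_inv * sigma2 + 1e-12 * np.eye(k)
    )
    beta_star = beta_hat + L @ rng.standard_normal(k)
    return X_mis @ beta_star + np.sqrt(sigma2) * rng.standard_normal(len(X_mis))


def _draw_pmm(
    rng: np.random.Generator, X_obs, y_obs, X_mis, donors: int
) -> np.ndarray:
    """Predictive mean matching: type-1 matching with a drawn beta."""
    n, k = X_obs.shape
    beta_hat, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ beta_hat
    dof = max(n - k, 1)
    sigma2 = resid @ resid / rng.chisquare(dof)
    XtX_inv = np.linalg.pinv(X_obs.T @ X_obs)
    L = np.linalg.cholesky(XtX_inv * sigma2 + 1e-12 * np.eye(k))
    beta_star = beta_hat + L @ rng.standard_normal(k)
    yhat_obs = X_obs @ beta_hat
    yhat_mis = X_mis @ beta_star
    order = np.argsort(yhat_obs, kind="stable")
    sorted_hat = yhat_obs[order]
    k_d = min(donors, len(y_obs))
    pos = np.searchsorted(sorted_hat, yhat_mis)
    out = np.empty(len(yhat_mis))
    lo = np.clip(pos - k_d, 0, len(sorted_hat))
    hi = np.clip(pos + k_d, 0, len(sorted_hat))
    for i in range(len(yhat_mis)):
        cand = np.arange(lo[i], hi[i])
        if len(cand) == 0:
            cand = np.arange(len(sorted_hat))
        d = np.abs(sorted_hat[cand] - yhat_mis[i])
        best = cand[np.argsort(d, kind="stable")[:k_d]]
        pick = best[rng.integers(len(best))]
        out[i] = y_obs[order[pick]]
    return out


def _fit_logistic(X, y, rng: np.random.Generator, multinomial: bool):
    """Bootstrap + (multinomial) logistic fit with ridge fallback."""
    idx = rng.integers(len(y), size=len(y))
    Xb, yb = X[idx], y[idx]
    if len(np.unique(yb)) < 2:  # degenerate bootstrap: fall back to original
        Xb, yb = X, y
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=200)
        clf.fit(Xb, yb)
        if not np.all(np.abs(clf.coef_) < 15.0):
            logger.info("perfect prediction detected; ridge-stabilised refit")
            clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=200)
            clf.fit(Xb, yb)
    return clf


def _impute_once(
    data: pd.DataFrame,
    meta: Mapping[str, VariableMeta],
    config: MIConfig,
    rng: np.random.Generator,
    targets: Sequence[str],
) -> pd.DataFrame:
    cur = data.copy()
    miss = {v: data[v].isna() for v in targets}
    # initial fill: draws from the observed margin
    for v in targets:
        obs = data[v].dropna().to_numpy()
        cur.loc[miss[v], v] = rng.choice(obs, size=int(miss[v].sum()))
    order = sorted(targets, key=lambda v: (miss[v].mean(), v))
    for _ in range(config.n_iterations):
        for v in order:
            mk = miss[v].to_numpy()
            if not mk.any():
                continue
            X = _encode_predictors(cur, meta, exclude=v)
            method = config.method_for(meta[v].var_type)
            if method in ("pmm", "norm"):
                y_obs = pd.to_numeric(data.loc[~miss[v], v]).to_numpy(dtype=float)
                if method == "norm":
                    draws = _draw_norm(rng, X[~mk], y_obs, X[mk])
                else:
                    draws = _draw_pmm(rng, X[~mk], y_obs, X[mk], config.pmm_donors)
                cur.loc[miss[v], v] = draws
            elif method == "logistic":
                y_obs = pd.to_numeric(data.loc[~miss[v], v]).to_numpy(dtype=int)
                if len(np.unique(y_obs)) < 2:
                    cur.loc[miss[v], v] = float(y_obs[0])
                    continue
                clf = _fit_logistic(X[~mk], y_obs, rng, multinomial=False)
                p1 = clf.predict_proba(X[mk])[:, list(clf.classes_).index(1)]
                cur.loc[miss[v], v] = (rng.random(int(mk.sum())) < p1).astype(float)
            elif method == "multinomial":
                y_obs = data.loc[~miss[v], v].to_numpy()
                classes = pd.unique(y_obs)
                if len(classes) < 2:
                    cur.loc[miss[v], v] = classes[0]
                    continue
                clf = _fit_logistic(X[~mk], y_obs, rng, multinomial=True)
                probs = clf.predict_proba(X[mk])
                u = rng.random((int(mk.sum()), 1))
                pick = (probs.cumsum(axis=1) < u).sum(axis=1)
                pick = np.minimum(pick, len(clf.classes_) - 1)
                cur.loc[miss[v], v] = clf.classes_[pick]
            else:
                raise ConfigError(f"methods: unknown method {method!r}")
    return cur


def impute(
    data: pd.DataFrame,
    meta: Mapping[str, VariableMeta],
    config: MIConfig,
    predictors_only: Sequence[str] = (),
) -> list[pd.DataFrame]:
    """Produce ``config.m`` completed copies of ``data``.

    ``predictors_only`` columns (e.g. the non-response indicator) must be
    fully observed; they enter every conditional model but are never
    imputed.  Chained-equation visits run in order of increasing missingness
    fraction.  Observed cells are returned bit-identical to the input, and
    the whole procedure is deterministic given ``config.seed``.
    """
    for c in data.columns:
        if c not in meta:
            raise ConfigError(f"no metadata/type declared for column {c!r}")
    for c in predictors_only:
        if data[c].isna().any():
            raise ConfigError(
                f"predictor-only column {c!r} must be fully observed"
            )
    targets = [
        c for c in data.columns
        if c not in set(predictors_only) and data[c].isna().any()
    ]
    for c in targets:
        if data[c].isna().all():
            raise ConfigError(
                f"variable {c!r} is 100% missing; exclude it before imputation"
            )
    if not targets:
        return [data.copy() for _ in range(config.m)]
    children = np.random.SeedSequence(config.seed).spawn(config.m)
    out = []
    for ss in children:
        rng = np.random.default_rng(ss)
        out.append(_impute_once(data, meta, config, rng, targets))
    return out


def delta_adjust(
    data: pd.DataFrame,
    meta: Mapping[str, VariableMeta],
    config: MIConfig,
    delta: float | Mapping[str, float],
    delta_config: DeltaConfig,
    predictors_only: Sequence[str] = (),
) -> list[pd.DataFrame]:
    """Impute, then shift imputed values of the target variable by ``delta``.

    Observed values are never shifted.  With ``delta_config.stratified``,
    ``delta`` maps stratum value to shift and each stratum moves
    independently.  A delta of 0 reproduces :func:`impute` exactly (same
    seed, same draws).
    """
    tv = delta_config.target_variable
    if tv not in data.columns:
        raise ConfigError(f"target_variable {tv!r} not in data")
    completed = impute(data, meta, config, predictors_only=predictors_only)
    was_missing = data[tv].isna()
    if not was_missing.any():
        warnings.warn(
            f"delta adjustment on {tv!r} is a no-op: no imputed values",
            RuntimeWarning,
            stacklevel=2,
        )
        return completed
    for df in completed:
        if delta_config.stratified:
            sv = delta_config.stratum_variable
            for stratum, d in dict(delta).items():
                sel = was_missing & (data[sv] == _coerce_stratum(data[sv], stratum))
                df.loc[sel, tv] = pd.to_numeric(df.loc[sel, tv]) + float(d)
        else:
            df.loc[was_missing, tv] = (
                pd.to_numeric(df.loc[was_missing, tv]) + float(delta)
            )
    return completed


def _coerce_stratum(col: pd.Series, stratum):
    if pd.api.types.is_numeric_dtype(col):
        return float(stratum)
    return stratum


def pooled_mean(
    completed: Sequence[pd.DataFrame], variable: str
) -> PooledEstimate:
    """Rubin-pooled mean of ``variable`` across completed datasets."""
    pts, vs = [], []
    for df in completed:
        x = pd.to_numeric(df[variable]).to_numpy(dtype=float)
        pts.append(float(x.mean()))
        vs.append(float(x.var(ddof=1) / len(x)))
    return pool(pts, vs)


def calibrate_delta(
    data: pd.DataFrame,
    meta: Mapping[str, VariableMeta],
    mi_config: MIConfig,
    delta_config: DeltaConfig,
    predictors_only: Sequence[str] = (),
) -> dict:
    """Find the delta that matches the pooled mean to the benchmark.

    Bisection on the (monotone, deterministic given the fixed MI seed)
    pooled-mean-of-target as a function of delta, to ``delta_config.tol`` on
    the mean scale.  With stratification, each stratum is calibrated
    independently against its own benchmark.  Returns a dict with the
    calibrated delta(s) and achieved pooled mean(s).
    """
    if delta_config.benchmark is None:
        raise ConfigError("benchmark: required for calibration")
    tv = delta_config.target_variable

    if delta_config.stratified:
        sv = delta_config.stratum_variable
        out = {"delta": {}, "achieved_mean": {}, "strata": []}
        for stratum, bench in dict(delta_config.benchmark).items():
            res = _calibrate_one(
                data, meta, mi_config, delta_config, float(bench),
                predictors_only, stratum=stratum,
            )
            out["delta"][stratum] = res["delta"]
            out["achieved_mean"][stratum] = res["achieved_mean"]
            out["strata"].append(stratum)
        return out
    return _calibrate_one(
        data, meta, mi_config, delta_config, float(delta_config.benchmark),
        predictors_only, stratum=None,
    )


def _calibrate_one(
    data, meta, mi_config, delta_config, benchmark, predictors_only, stratum
):
    tv = delta_config.target_variable
    sv = delta_config.stratum_variable

    def g(delta: float) -> float:
        if stratum is None:
            completed = delta_adjust(
                data, meta, mi_config, delta, delta_config, predictors_only
            )
            return pooled_mean(completed, tv).point
        d = {stratum: delta}
        completed = delta_adjust(
            data, meta, mi_config, d, delta_config, predictors_only
        )
        sel = data[sv] == _coerce_stratum(data[sv], stratum)
        pts = [float(pd.to_numeric(df.loc[sel, tv]).mean()) for df in completed]
        return float(np.mean(pts))

    lo, hi = delta_config.bracket
    glo, ghi = g(lo) - benchmark, g(hi) - benchmark
    if glo == 0:
        return {"delta": lo, "achieved_mean": benchmark, "stratum": stratum}
    if ghi == 0:
        return {"delta": hi, "achieved_mean": benchmark, "stratum": stratum}
    if np.sign(glo) == np.sign(ghi):
        raise ConvergenceError(
            f"benchmark {benchmark} outside attainable pooled-mean range "
            f"[{min(glo, ghi) + benchmark:.4f}, {max(glo, ghi) + benchmark:.4f}] "
            f"over bracket {delta_config.bracket}"
        )
    for _ in range(delta_config.max_iter):
        mid = 0.5 * (lo + hi)
        gm = g(mid) - benchmark
        if abs(gm) < delta_config.tol:
            return {"delta": mid, "achieved_mean": gm + benchmark,
                    "stratum": stratum}
        if np.sign(gm) == np.sign(glo):
            lo, glo = mid, gm
        else:
            hi = mid
    return {"delta": 0.5 * (lo + hi), "achieved_mean": g(0.5 * (lo + hi)),
            "stratum": stratum}
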