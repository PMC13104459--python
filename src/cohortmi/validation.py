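"""Internal validation by "traveling back in time".

An early-sweep quantity (a mean, a category percentage, or covariate-class
hazard ratios for later mortality) is estimated three ways:

* **truth** — on every member alive and not emigrated at the target sweep
  (the per-sweep target population), using their actually observed values;
* **complete case** — after discarding the values of members who did not
  respond at the target sweep, i.e. what an analyst of that sweep would see;
* **MI** — after multiply imputing the discarded values with a set of
  auxiliary variables (typically the output of the three-stage selection)
  plus the fully observed non-response indicator.

Comparing the three quantifies non-response bias and how much of it the
auxiliaries recover: ``bias_cc = cc - truth``, ``bias_mi = mi - truth`` and
``relative_bias_reduction = 1 - |bias_mi|/|bias_cc|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .cohort import (CohortTable, RESPONDENT, VariableMeta,
                     derive_nonresponse, prior_participation)
from .design import build_design
from .errors import ConfigError
from .mi import MIConfig, PooledEstimate, impute, pool
from .poisson import Z975


@dataclass(frozen=True)
class Estimand:
    """What to estimate in each arm of the validation.

    ``kind`` is ``mean`` (mean of a continuous variable),
    ``category_percentage`` (percentage of members in ``category`` of a
    categorical variable), or ``cox_hr`` (hazard ratios of ``variable``'s
    levels on the survival outcome, adjusted for ``adjustment``).
    """

    kind: str
    variable: str
    category: str | None = None
    adjustment: tuple[str, ...] = ()
    duration: str | None = None
    event: str | None = None
    entry_time: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("mean", "category_percentage", "cox_hr"):
            raise ConfigError(f"kind: unknown estimand kind {self.kind!r}")
        if self.kind == "category_percentage" and self.category is None:
            raise ConfigError("category: required for category_percentage")
        if self.kind == "cox_hr" and (self.duration is None or self.event is None):
            raise ConfigError("duration/event: required for cox_hr")


@dataclass
class ValidationReport:
    """Truth / complete-case / MI estimates with bias metrics.

    One row per reported quantity (a single row for means and percentages,
    one per non-reference exposure level for hazard ratios).  Ratio-scale
    quantities are carried on the log scale in ``truth``/``cc``/``mi`` and
    exponentiated in :meth:`summary`.
    """

    estimand: Estimand
    target_sweep: int
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows).set_index("quantity")

    def summary(self) -> pd.DataFrame:
        df = self.to_frame()
        if self.estimand.kind == "cox_hr":
            for col in ("truth", "cc", "mi"):
                df[f"{col}_hr"] = np.exp(df[col])
        return df

    def render_text(self) -> str:
        """Plain-text four-column layout: truth, complete-case, MI, biases."""
        lines = [
            f"estimand: {self.estimand.kind} of {self.estimand.variable} "
            f"(target sweep {self.target_sweep})"
        ]
        for r in self.rows:
            lines.append(
                f"  {r['quantity']:<30} truth={r['truth']:9.4f}  "
                f"cc={r['cc']:9.4f}  mi={r['mi']:9.4f}  "
                f"bias_cc={r['bias_cc']:+.4f}  bias_mi={r['bias_mi']:+.4f}"
            )
        return "\n".join(lines)


def composite_score(components: pd.DataFrame) -> pd.Series:
    """First principal component of standardised test scores.

    Computed among members with every component observed; standardised to
    mean 0 and unit variance in that estimation sample, with the sign fixed
    so the score correlates positively with the first component.  Constant
    components are dropped with a warning.
    """
    comps = components.copy()
    keep = []
    for c in comps.columns:
        sd = comps[c].std()
        if not np.isfinite(sd) or sd == 0:
            warnings.warn(
                f"component {c!r} is constant; dropped from the composite",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        keep.append(c)
    if len(keep) < 2:
        raise ConfigError("composite_score needs at least two varying components")
    comps = comps[keep]
    complete = comps.dropna()
    z = (complete - complete.mean()) / complete.std(ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    loading = evecs[:, -1]
    score = z.to_numpy() @ loading
    if np.corrcoef(score, z.iloc[:, 0].to_numpy())[0, 1] < 0:
        score = -score
    score = (score - score.mean()) / score.std(ddof=1)
    out = pd.Series(np.nan, index=components.index, name="composite")
    out.loc[complete.index] = score
    return out


def fit_cox(
    data: pd.DataFrame,
    duration: str,
    event: str,
    covariates: Sequence[str],
    meta: Mapping[str, VariableMeta],
    entry_time: float | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit via partial likelihood (lifelines).

    Categorical covariates expand to reference-coded indicators.  With
    ``entry_time`` set, members are left-truncated at that time (only those
    still at risk then are used, entering the risk set at it).  Levels with
    no events are dropped from the comparison with a warning, since their
    partial likelihood is monotone.  Returns a per-term frame of log-HRs,
    SEs, HRs, 95% CIs and p-values.
    """
    df = data.copy()
    if entry_time is not None:
        df = df[pd.to_numeric(df[duration]) > entry_time].copy()
        df["_entry"] = float(entry_time)
    # drop exposure levels without events (monotone likelihood)
    for cov in covariates:
        if meta[cov].var_type != "categorical":
            continue
        ev = pd.to_numeric(df[event])
        for lv in (meta[cov].category_labels or []):
            sel = df[cov] == lv
            if sel.any() and ev[sel].sum() == 0:
                warnings.warn(
                    f"level {lv!r} of {cov!r} has no events; dropped",
                    RuntimeWarning,
                    stacklevel=2,
                )
                df = df[~sel]
    X = build_design(df, list(covariates), meta, add_intercept=False)
    # indicators of dropped levels are all-zero; remove them
    X = X.loc[:, X.nunique() > 1]
    fitframe = X.copy()
    fitframe[duration] = pd.to_numeric(df[duration])
    fitframe[event] = pd.to_numeric(df[event])
    kwargs = {}
    if entry_time is not None:
        fitframe["_entry"] = df["_entry"]
        kwargs["entry_col"] = "_entry"
    fitframe = fitframe.dropna()
    cph = CoxPHFitter()
    cph.fit(fitframe, duration_col=duration, event_col=event, **kwargs)
    s = cph.summary
    out = pd.DataFrame(
        {
            "beta": s["coef"],
            "se": s["se(coef)"],
            "hr": np.exp(s["coef"]),
            "hr_lo": np.exp(s["coef"] - Z975 * s["se(coef)"]),
            "hr_hi": np.exp(s["coef"] + Z975 * s["se(coef)"]),
            "p": s["p"],
        }
    )
    out.index.name = "term"
    return out


def _estimate(
    estimand: Estimand,
    df: pd.DataFrame,
    meta: Mapping[str, VariableMeta],
) -> list[tuple[str, float, float]]:
    """(quantity, point, variance) rows for one dataset."""
    if estimand.kind == "mean":
        x = pd.to_numeric(df[estimand.variable]).dropna()
        return [(f"mean({estimand.variable})", float(x.mean()),
                 float(x.var(ddof=1) / len(x)))]
    if estimand.kind == "category_percentage":
        s = df[estimand.variable].dropna()
        n = len(s)
        p = float((s == estimand.category).mean())
        var = p * (1 - p) / n * 100.0**2
        return [(f"%({estimand.variable}={estimand.category})", 100.0 * p, var)]
    # cox_hr: one row per non-reference level / per covariate column
    covs = [estimand.variable, *estimand.adjustment]
    res = fit_cox(
        df, estimand.duration, estimand.event, covs, meta,
        entry_time=estimand.entry_time,
    )
    rows = []
    prefix = f"{estimand.variable}["
    for term, r in res.iterrows():
        if term.startswith(prefix) or term == estimand.variable:
            rows.append((f"logHR({term})", float(r["beta"]),
                         float(r["se"] ** 2)))
    return rows


def travel_back(
    cohort: CohortTable,
    estimand: Estimand,
    target_sweep: int,
    auxiliaries: Sequence[str],
    mi_config: MIConfig | None = None,
) -> ValidationReport:
    """Truth / complete-case / MI comparison for one estimand.

    The truth sample is everyone alive and not emigrated at the target
    sweep.  The complete-case arm discards non-respondents of that sweep;
    the MI arm pretends the estimand values of those non-respondents are
    missing and imputes them from the auxiliaries plus the non-response
    indicator, pooling estimates by Rubin's rules.
    """
    mi_config = mi_config or MIConfig()
    if estimand.variable not in cohort.values.columns:
        raise ConfigError(f"estimand variable {estimand.variable!r} unavailable")
    _, nr = derive_nonresponse(cohort, target_sweep)
    elig = cohort.eligible(target_sweep)
    resp = cohort.status[target_sweep] == RESPONDENT

    needed = [estimand.variable, *estimand.adjustment]
    if estimand.kind == "cox_hr":
        needed += [estimand.duration, estimand.event]
    needed = list(dict.fromkeys(needed))
    aux = [a for a in auxiliaries if a not in needed]
    meta = dict(cohort.meta)
    values = cohort.values
    if "prior_incomplete" in aux and "prior_incomplete" not in values.columns:
        # prior-participation auxiliary is derived, not stored
        values = values.copy()
        values["prior_incomplete"] = prior_participation(cohort, target_sweep)
        meta["prior_incomplete"] = VariableMeta("prior_incomplete", 1, "binary")
    unknown = [a for a in aux if a not in values.columns]
    if unknown:
        raise ConfigError(f"unknown auxiliaries: {unknown}")

    truth_df = values.loc[elig, needed + aux]
    truth_rows = _estimate(estimand, truth_df, meta)
    cc_rows = _estimate(estimand, values.loc[resp, needed + aux], meta)

    if (nr[elig] == 1).any():
        mi_data = truth_df.copy()
        nonresp_idx = nr[elig] == 1
        mi_data.loc[nonresp_idx, estimand.variable] = np.nan
        nr_name = f"nonresponse_s{target_sweep}"
        mi_data[nr_name] = nr[elig]
        mi_meta = {v: meta[v] for v in needed + aux}
        mi_meta[nr_name] = VariableMeta(nr_name, target_sweep, "binary")
        completed = impute(
            mi_data, mi_meta, mi_config,
            predictors_only=[nr_name],
        )
        per_imp = [_estimate(estimand, df, meta) for df in completed]
        mi_rows = []
        for i, (q, _, _) in enumerate(per_imp[0]):
            est = pool([r[i][1] for r in per_imp], [r[i][2] for r in per_imp])
            mi_rows.append((q, est.point, est.T))
    else:
        mi_rows = truth_rows  # zero non-response: all three arms coincide

    report = ValidationReport(estimand=estimand, target_sweep=target_sweep)
    for (q, t, tv), (_, c, cv), (_, m, mv) in zip(truth_rows, cc_rows, mi_rows):
        bias_cc = c - t
        bias_mi = m - t
        rbr = (1.0 - abs(bias_mi) / abs(bias_cc)) if bias_cc != 0 else np.nan
        report.rows.append(
            {
                "quantity": q,
                "truth": t,
                "truth_se": float(np.sqrt(tv)),
                "cc": c,
                "cc_se": float(np.sqrt(cv)),
                "mi": m,
                "mi_se": float(np.sqrt(mv)),
                "bias_cc": bias_cc,
                "bias_mi": bias_mi,
                "relative_bias_reduction": rbr,
            }
        )
    return report
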