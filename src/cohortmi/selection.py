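"""Three-stage selection of auxiliary variables predicting non-response.

For a target sweep *t* the procedure screens candidate predictors collected
at sweeps ``1..t-1`` through successively stricter risk-ratio models of the
non-response indicator at *t* (eligible members only):

* **Stage 1** — univariable modified Poisson regression per candidate,
  complete cases; keep when p < 0.001.
* **Stage 2** — one multivariable model per origin sweep containing all of
  that sweep's stage-1 survivors, complete cases; keep when p < 0.05.
* **Stage 3** — multiply impute the retained variables (with the fully
  observed non-response indicator appended to every imputation model); per
  origin sweep *s*, fit the multivariable model of non-response on sweep-*s*
  survivors adjusted for all retained variables from earlier (never later)
  sweeps, pool by Rubin's rules; keep when pooled p < 0.001.

Four variables — sex, country of birth, participation in all previous
sweeps (the single binary "incomplete vs complete response"), and father's
socioeconomic status — skip stages 1-2 and enter stage 3 a priori.

Categorical variables are kept or dropped as whole terms using the minimum
level-wise Wald p-value.  A *consistent* predictor over a period of sweeps
is one selected for strictly more than half of the target sweeps at which it
could have been a predictor (target sweep after its origin sweep).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import poisson
from .cohort import CohortTable, VariableMeta, derive_nonresponse, prior_participation
from .design import build_design, term_columns
from .errors import ConfigError, RankError
from .mi import MIConfig, PooledEstimate, impute, pool

logger = logging.getLogger(__name__)

PRIOR_VAR = "prior_incomplete"
DEFAULT_APRIORI = ("sex", "country", PRIOR_VAR, "father_social_class")


@dataclass(frozen=True)
class SelectionConfig:
    p1: float = 0.001
    p2: float = 0.05
    p3: float = 0.001
    apriori: tuple[str, ...] = DEFAULT_APRIORI
    force_retain_apriori: bool = True
    consistency_fraction: float = 0.5  # strict "more than half"
    period_split: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"early": (2, 4), "late": (5, 10)}
    )

    def __post_init__(self) -> None:
        for f in ("p1", "p2", "p3"):
            v = getattr(self, f)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{f} must be in (0,1), got {v}")


@dataclass
class StageResult:
    """Per-stage audit: kept variables per origin sweep plus all fits."""

    kept: dict[int, list[str]]
    fits: dict[str, object]  # variable -> FitResult | dict[str, PooledEstimate]
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def kept_flat(self) -> list[str]:
        return [v for s in sorted(self.kept) for v in self.kept[s]]


@dataclass
class SelectionTrace:
    """Full audit of a per-target-sweep selection run."""

    target_sweep: int
    stage1: StageResult
    stage2: StageResult
    stage3: StageResult
    apriori_used: list[str]
    final: list[str]


def _candidate_names(
    meta: Mapping[str, VariableMeta],
    target_sweep: int,
    apriori: Sequence[str],
) -> dict[int, list[str]]:
    """Candidates grouped by origin sweep; a-priori variables skipped."""
    out: dict[int, list[str]] = {}
    for name, m in meta.items():
        if name in apriori or m.origin_sweep >= target_sweep:
            continue
        out.setdefault(m.origin_sweep, []).append(name)
    for s in out:
        out[s] = sorted(out[s])
    return out


def stage1(
    cohort: CohortTable,
    candidates: Mapping[str, VariableMeta],
    target_sweep: int,
    config: SelectionConfig,
) -> StageResult:
    """Univariable complete-case screen of every candidate at ``p1``."""
    _, outcome = derive_nonresponse(cohort, target_sweep)
    groups = _candidate_names(candidates, target_sweep, config.apriori)
    kept: dict[int, list[str]] = {}
    fits: dict[str, object] = {}
    dropped: dict[str, str] = {}
    for s, names in groups.items():
        for name in names:
            X = build_design(cohort.values, [name], candidates)
            try:
                fr = poisson.fit(outcome, X)
            except Exception as exc:
                dropped[name] = f"fit error: {exc}"
                continue
            fits[name] = fr
            if not fr.converged:
                dropped[name] = "non-convergence"
                logger.info("stage 1: %s excluded (%s)", name, fr.diagnostics)
                continue
            cols = term_columns(name, candidates)
            if fr.p_for(cols) < config.p1:
                kept.setdefault(s, []).append(name)
    return StageResult(kept=kept, fits=fits, dropped=dropped)


def _fit_full_rank(outcome, data, names, meta, dropped: dict[str, str]):
    """Fit a multivariable model, greedily dropping later-entered collinear
    variables until the design has full rank."""
    use = list(names)
    while use:
        X = build_design(data, use, meta)
        try:
            return use, poisson.fit(outcome, X)
        except RankError as exc:
            offending = [
                v for v in reversed(use)
                if any(c in str(exc) for c in term_columns(v, meta))
            ]
            if not offending:
                raise
            victim = offending[0]
            use.remove(victim)
            dropped[victim] = "collinear; dropped from multivariable model"
            logger.info("dropping collinear term %s", victim)
    raise ConfigError("no terms left after collinearity pruning")


def stage2(
    cohort: CohortTable,
    stage1_result: StageResult,
    candidates: Mapping[str, VariableMeta],
    target_sweep: int,
    config: SelectionConfig,
) -> StageResult:
    """Per-origin-sweep multivariable complete-case screen at ``p2``."""
    _, outcome = derive_nonresponse(cohort, target_sweep)
    kept: dict[int, list[str]] = {}
    fits: dict[str, object] = {}
    dropped: dict[str, str] = {}
    for s, names in sorted(stage1_result.kept.items()):
        if not names:
            continue
        use, fr = _fit_full_rank(outcome, cohort.values, names, candidates, dropped)
        if not fr.converged:
            for name in use:
                dropped[name] = "stage-2 model non-convergence"
            continue
        for name in use:
            fits[name] = fr
            if fr.p_for(term_columns(name, candidates)) < config.p2:
                kept.setdefault(s, []).append(name)
    return StageResult(kept=kept, fits=fits, dropped=dropped)


def stage3(
    cohort: CohortTable,
    stage2_result: StageResult,
    target_sweep: int,
    config: SelectionConfig,
    mi_config: MIConfig,
) -> tuple[StageResult, list[str]]:
    """MI-based final screen at ``p3``; returns the stage audit and the
    final predictor set (a-priori variables force-retained by default)."""
    retained = stage2_result.kept_flat
    work = cohort.copy()
    apriori = [a for a in config.apriori if a in work.meta or a == PRIOR_VAR]
    if PRIOR_VAR in apriori:
        work.values[PRIOR_VAR] = prior_participation(work, target_sweep)
        work.meta[PRIOR_VAR] = VariableMeta(PRIOR_VAR, 1, "binary")
    apriori = [a for a in apriori if a in work.meta]
    variables = list(dict.fromkeys(retained + apriori))
    elig = work.eligible(target_sweep)
    _, outcome = derive_nonresponse(work, target_sweep)
    data = work.values.loc[elig, variables].copy()
    meta = {v: work.meta[v] for v in variables}
    nr_name = f"nonresponse_s{target_sweep}"
    data[nr_name] = outcome[elig]
    meta[nr_name] = VariableMeta(nr_name, target_sweep, "binary")

    if data[variables].isna().any().any():
        completed = impute(
            data, meta, mi_config, predictors_only=[nr_name]
        )
    else:
        completed = [data]  # complete data: single fit, B = 0

    by_sweep: dict[int, list[str]] = {}
    for v in variables:
        by_sweep.setdefault(meta[v].origin_sweep, []).append(v)

    fits: dict[str, dict[str, PooledEstimate]] = {}
    kept: dict[int, list[str]] = {}
    dropped: dict[str, str] = {}
    for s in sorted(by_sweep):
        terms = [v for v in variables if meta[v].origin_sweep <= s]
        own = by_sweep[s]
        # prune collinear terms once, on the first completed dataset, so the
        # design is identical across imputations and pooling lines up
        use, first = _fit_full_rank_df(
            outcome[elig], completed[0], terms, meta, dropped
        )
        per_imp: list[poisson.FitResult] = [first]
        for df in completed[1:]:
            X = build_design(df, use, meta)
            per_imp.append(poisson.fit(outcome[elig].reindex(df.index), X))
        if any(not fr.converged for fr in per_imp):
            for v in own:
                dropped[v] = "stage-3 model non-convergence"
            continue
        pooled = _pool_fits(per_imp)
        for v in own:
            cols = term_columns(v, meta)
            present = {c: pooled[c] for c in cols if c in pooled}
            if not present:  # pruned as collinear
                dropped.setdefault(v, "collinear; dropped from stage-3 model")
                continue
            fits[v] = present
            pmin = min(est.p for est in present.values())
            if pmin < config.p3:
                kept.setdefault(s, []).append(v)
    result = StageResult(kept=kept, fits=fits, dropped=dropped)
    final = list(dict.fromkeys(result.kept_flat))
    if config.force_retain_apriori:
        final = list(dict.fromkeys(final + apriori))
    return result, final


def _fit_full_rank_df(outcome, df, names, meta, dropped):
    use = list(names)
    outcome = outcome.reindex(df.index)
    while use:
        X = build_design(df, use, meta)
        try:
            return use, poisson.fit(outcome, X)
        except RankError as exc:
            offending = [
                v for v in reversed(use)
                if any(c in str(exc) for c in term_columns(v, meta))
            ]
            if not offending:
                raise
            use.remove(offending[0])
            dropped[offending[0]] = "collinear; dropped from stage-3 model"
    raise ConfigError("no terms left after collinearity pruning")


def _pool_fits(per_imp: list[poisson.FitResult]) -> dict[str, PooledEstimate]:
    """Rubin-pool per-term log-RR estimates across imputations."""
    pooled: dict[str, PooledEstimate] = {}
    terms = per_imp[0].terms
    if len(per_imp) == 1:
        fr = per_imp[0]
        for i, t in enumerate(terms):
            pooled[t] = PooledEstimate(
                point=float(fr.beta[i]), W=float(fr.robust_se[i] ** 2),
                B=0.0, m=2,
            )
        return pooled
    for i, t in enumerate(terms):
        pts = [fr.beta[i] for fr in per_imp]
        vs = [fr.robust_se[i] ** 2 for fr in per_imp]
        pooled[t] = pool(pts, vs)
    return pooled


def run_selection(
    cohort: CohortTable,
    candidates: Mapping[str, VariableMeta],
    target_sweep: int,
    config: SelectionConfig | None = None,
    mi_config: MIConfig | None = None,
) -> SelectionTrace:
    """Run stages 1-3 for one target sweep and assemble the audit trace."""
    config = config or SelectionConfig()
    mi_config = mi_config or MIConfig()
    s1 = stage1(cohort, candidates, target_sweep, config)
    s2 = stage2(cohort, s1, candidates, target_sweep, config)
    s3, final = stage3(cohort, s2, target_sweep, config, mi_config)
    apriori = [a for a in config.apriori
               if a in cohort.meta or a == PRIOR_VAR]
    return SelectionTrace(
        target_sweep=target_sweep,
        stage1=s1,
        stage2=s2,
        stage3=s3,
        apriori_used=apriori,
        final=final,
    )


def consistent_predictors(
    traces: Sequence[SelectionTrace],
    meta: Mapping[str, VariableMeta],
    config: SelectionConfig | None = None,
) -> dict[str, list[str]]:
    """Variables selected in strictly more than half of their possible
    target sweeps, per period.

    A sweep is *possible* for a variable when the target sweep lies in the
    period, is covered by the supplied traces, and is after the variable's
    origin sweep.
    """
    config = config or SelectionConfig()
    covered = {tr.target_sweep: tr for tr in traces}
    out: dict[str, list[str]] = {}
    names = set()
    for tr in traces:
        names.update(tr.final)
    for period, (a, b) in config.period_split.items():
        targets = [t for t in range(a, b + 1) if t in covered]
        consistent = []
        for name in sorted(names):
            origin = meta[name].origin_sweep if name in meta else 1
            possible = [t for t in targets if t > origin]
            if not possible:
                continue
            hits = sum(1 for t in possible if name in covered[t].final)
            if hits > config.consistency_fraction * len(possible):
                consistent.append(name)
        out[period] = consistent
    return out
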