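"""Eligibility screening of candidate predictors of non-response.

Large multi-sweep cohorts carry tens of thousands of variables; before any
model-based selection the pool is reduced by structural rules:

* routed variables (questions asked only conditional on a prior answer) are
  excluded — their missingness encodes routing, not non-response;
* constituents of composite index/score variables are excluded whenever the
  composite itself is in the pool;
* binary variables with minority-class prevalence below a threshold
  (default 1%) are excluded as near-constant;
* variables missing for more than a threshold fraction (default 40%) of the
  members eligible at their origin sweep are excluded;
* categorical variables with a level below a minimum fraction (default 1%)
  are recoded when possible — ordered levels merge into the nearest
  neighbour, unordered into the modal level — and excluded otherwise.

Every decision is recorded, never raised, so a screening run yields a full
audit of the input pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .cohort import CohortTable, VariableMeta
from .errors import ConfigError

DECISIONS = (
    "kept",
    "excluded_routed",
    "excluded_constituent",
    "excluded_prevalence",
    "excluded_missing",
    "recoded",
    "excluded_unrecodable",
)


@dataclass(frozen=True)
class ScreeningConfig:
    min_binary_prevalence: float = 0.01
    max_missing_fraction: float = 0.40
    min_category_fraction: float = 0.01
    recode_strategy: str = "merge_adjacent"  # or merge_to_mode, drop_variable

    def __post_init__(self) -> None:
        for f in (
            "min_binary_prevalence",
            "max_missing_fraction",
            "min_category_fraction",
        ):
            v = getattr(self, f)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{f} must be in (0,1), got {v}")
        if self.recode_strategy not in (
            "merge_adjacent",
            "merge_to_mode",
            "drop_variable",
        ):
            raise ConfigError(
                f"recode_strategy: unknown strategy {self.recode_strategy!r}"
            )


@dataclass
class ScreeningResult:
    """Outcome of a screening pass.

    ``report`` maps variable name to its decision; ``cohort`` is a copy of
    the input with recoded categorical columns; ``meta`` covers the kept
    (and recoded) variables only.
    """

    report: pd.DataFrame
    cohort: CohortTable
    meta: dict[str, VariableMeta] = field(default_factory=dict)

    @property
    def kept(self) -> list[str]:
        ok = self.report["decision"].isin(["kept", "recoded"])
        return list(self.report.index[ok])

    def counts(self) -> pd.Series:
        return self.report["decision"].value_counts().reindex(
            DECISIONS, fill_value=0
        )


def prevalence(values: pd.Series) -> float:
    """Minority-class fraction of a binary variable among non-missing values.

    Symmetric by design: a variable that is 99.5% ones is as uninformative
    as one that is 0.5% ones.  Returns NaN when every value is missing.
    """
    v = values.dropna()
    if v.empty:
        return float("nan")
    vals = pd.to_numeric(v, errors="coerce")
    uniq = set(vals.unique())
    if any(pd.isna(u) for u in uniq) or not uniq <= {0.0, 1.0}:
        raise TypeError("prevalence expects a 0/1-coded binary variable")
    ones = int((vals == 1).sum())
    return min(ones, len(vals) - ones) / len(vals)


def _recode_categorical(
    values: pd.Series,
    m: VariableMeta,
    min_frac: float,
    strategy: str,
    ordered: bool,
) -> tuple[pd.Series, VariableMeta] | None:
    """Merge sub-threshold levels; None when recoding is impossible."""
    obs = values.dropna()
    if m.var_type == "ordinal":
        levels = (
            list(range(len(m.category_labels)))
            if m.category_labels
            else sorted(obs.unique())
        )
    else:
        levels = list(m.category_labels or pd.unique(obs))
    if len(levels) <= 2:
        return None  # a binary categorical has nothing to merge into
    vals = values.copy()
    while True:
        obs = vals.dropna()
        freqs = obs.value_counts(normalize=True).reindex(levels, fill_value=0.0)
        low = [lv for lv in levels if freqs[lv] < min_frac]
        if not low:
            break
        if len(levels) <= 2:
            return None
        lv = min(low, key=lambda l: freqs[l])
        i = levels.index(lv)
        if ordered or strategy == "merge_adjacent":
            # merge into nearest neighbour (larger of the two when interior)
            cand = [j for j in (i - 1, i + 1) if 0 <= j < len(levels)]
            tgt = levels[max(cand, key=lambda j: freqs[levels[j]])]
        else:
            mode = freqs.drop(lv).idxmax()
            tgt = mode
        vals = vals.replace(lv, tgt)
        levels.remove(lv)
    if m.var_type == "ordinal":
        # renumber codes compactly
        mapping = {old: new for new, old in enumerate(levels)}
        vals = vals.map(lambda x: mapping.get(x, np.nan))
        labels = tuple(
            (m.category_labels[int(old)] if m.category_labels else str(old))
            for old in levels
        )
    else:
        labels = tuple(str(lv) for lv in levels)
    new_meta = VariableMeta(
        name=m.name,
        origin_sweep=m.origin_sweep,
        var_type=m.var_type,
        routed=m.routed,
        composite_of=m.composite_of,
        category_labels=labels,
    )
    return vals, new_meta


def screen(
    cohort: CohortTable,
    meta: Mapping[str, VariableMeta] | None = None,
    config: ScreeningConfig | None = None,
) -> ScreeningResult:
    """Apply the structural eligibility rules to every variable.

    Missingness is computed over the members eligible (alive, not emigrated)
    at the variable's origin sweep; binary prevalence over non-missing
    values.  Decisions partition the variable set and are all recorded in
    the report.
    """
    config = config or ScreeningConfig()
    meta = dict(meta or cohort.meta)
    out = cohort.copy()
    composites_present = {
        c
        for m in meta.values()
        if m.composite_of
        for c in m.composite_of
        if m.name in out.values.columns
    }
    decisions: dict[str, str] = {}
    detail: dict[str, str] = {}
    kept_meta: dict[str, VariableMeta] = {}
    for name in out.values.columns:
        m = meta[name]
        if m.routed:
            decisions[name] = "excluded_routed"
            continue
        if name in composites_present:
            decisions[name] = "excluded_constituent"
            continue
        elig = out.eligible(min(m.origin_sweep, out.n_sweeps))
        col = out.values.loc[elig, name]
        miss = float(col.isna().mean()) if len(col) else 1.0
        if miss > config.max_missing_fraction:
            decisions[name] = "excluded_missing"
            detail[name] = f"missing={miss:.3f}"
            continue
        if m.var_type == "binary":
            prev = prevalence(col)
            if np.isnan(prev) or prev < config.min_binary_prevalence:
                decisions[name] = "excluded_prevalence"
                detail[name] = f"prevalence={prev:.5f}"
                continue
            decisions[name] = "kept"
            kept_meta[name] = m
            continue
        if m.var_type in ("categorical", "ordinal"):
            obs = col.dropna()
            if m.var_type == "ordinal":
                labels = list(range(len(m.category_labels or []))) or sorted(
                    pd.unique(obs)
                )
            else:
                labels = list(m.category_labels or pd.unique(obs))
            freqs = obs.value_counts(normalize=True).reindex(
                labels, fill_value=0.0
            )
            if (freqs < config.min_category_fraction).any():
                if config.recode_strategy == "drop_variable":
                    decisions[name] = "excluded_unrecodable"
                    continue
                rec = _recode_categorical(
                    out.values[name],
                    m,
                    config.min_category_fraction,
                    config.recode_strategy,
                    ordered=m.var_type == "ordinal",
                )
                if rec is None:
                    decisions[name] = "excluded_unrecodable"
                    continue
                out.values[name], new_m = rec
                out.meta[name] = new_m
                decisions[name] = "recoded"
                kept_meta[name] = new_m
                continue
        decisions[name] = "kept"
        kept_meta[name] = m
    report = pd.DataFrame(
        {
            "decision": pd.Series(decisions),
            "detail": pd.Series(detail).reindex(decisions.keys(), fill_value=""),
        }
    )
    report.index.name = "variable"
    return ScreeningResult(report=report, cohort=out, meta=kept_meta)
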