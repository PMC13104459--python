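"""Core cohort data model: wide member-by-variable values plus per-sweep status.

A multi-sweep cohort is represented as

* ``values`` -- a :class:`pandas.DataFrame` indexed by member id, one column
  per variable.  Missing entries are ``NaN`` (numeric columns) or ``None``
  (categorical label columns); no magic numbers.
* ``status`` -- a member x sweep grid with one of four codes per cell:
  ``R`` (respondent), ``N`` (non-respondent), ``D`` (dead), ``E`` (emigrated).
* ``meta`` -- one :class:`VariableMeta` per value column, driving screening
  and the choice of imputation model.

Sweep numbering is 1-based with sweep 1 the birth sweep.  Death is always an
absorbing state; emigration is absorbing by default but can be relaxed.

The *eligible sample* at a sweep is everyone alive and not emigrated, i.e.
members whose status is ``R`` or ``N``; dead and emigrated members are
excluded from all non-response analyses because the target population at each
sweep is the cohort members still alive and resident.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, SchemaError

RESPONDENT = "R"
NONRESPONDENT = "N"
DEAD = "D"
EMIGRATED = "E"
_STATUS_CODES = frozenset({RESPONDENT, NONRESPONDENT, DEAD, EMIGRATED})

VAR_TYPES = ("continuous", "binary", "categorical", "ordinal")


@dataclass(frozen=True)
class VariableMeta:
    """Per-variable metadata.

    Parameters
    ----------
    name:
        Column name in the cohort value grid.
    origin_sweep:
        1-based sweep at which the variable was collected.
    var_type:
        One of ``continuous``, ``binary``, ``categorical``, ``ordinal``.
        Binary variables are coded 0/1, ordinal variables as numeric codes
        ``0..k-1`` (with ``category_labels`` naming the levels in order),
        categorical variables as label strings.
    routed:
        True when the question was only asked conditional on a prior answer;
        routed variables are excluded from candidate-predictor pools.
    composite_of:
        For index/score variables, the names of the constituent items.  When
        a composite is available its constituents are dropped from candidate
        pools in favour of the composite.
    category_labels:
        Ordered labels for categorical/ordinal variables.  The first label is
        the reference level in regression design matrices.
    """

    name: str
    origin_sweep: int
    var_type: str
    routed: bool = False
    composite_of: tuple[str, ...] | None = None
    category_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.var_type not in VAR_TYPES:
            raise SchemaError(
                f"variable {self.name!r}: unknown var_type {self.var_type!r}"
            )
        if self.origin_sweep < 1:
            raise SchemaError(
                f"variable {self.name!r}: origin_sweep must be >= 1"
            )
        if self.composite_of and self.name in self.composite_of:
            raise SchemaError(
                f"variable {self.name!r}: composite_of references itself"
            )


@dataclass(frozen=True)
class SweepFrame:
    """Participation accounting for one sweep.

    ``eligible_n`` is the total cohort minus deaths and emigrations at the
    sweep, and always equals ``respondents_n + nonrespondents_n``.
    """

    sweep: int
    eligible_n: int
    respondents_n: int
    nonrespondents_n: int

    def __post_init__(self) -> None:
        if self.eligible_n != self.respondents_n + self.nonrespondents_n:
            raise ConsistencyError(
                f"sweep {self.sweep}: eligible {self.eligible_n} != "
                f"respondents {self.respondents_n} + "
                f"non-respondents {self.nonrespondents_n}"
            )

    @classmethod
    def from_counts(
        cls, sweep: int, total: int, dead: int, emigrated: int, respondents: int
    ) -> "SweepFrame":
        """Derive the frame from printed participation counts.

        ``eligible = total - dead - emigrated`` and non-respondents are the
        eligible remainder after respondents.
        """
        eligible = total - dead - emigrated
        return cls(
            sweep=sweep,
            eligible_n=eligible,
            respondents_n=respondents,
            nonrespondents_n=eligible - respondents,
        )

    @property
    def response_rate(self) -> float:
        return self.respondents_n / self.eligible_n

    @property
    def nonresponse_rate(self) -> float:
        return self.nonrespondents_n / self.eligible_n


class CohortTable:
    """Wide cohort table with per-sweep vital/response status.

    Validates on construction: statuses are legal codes, death (and by
    default emigration) is absorbing, and every value column has metadata.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        status: pd.DataFrame,
        meta: Mapping[str, VariableMeta],
        emigration_absorbing: bool = True,
    ) -> None:
        if not values.index.equals(status.index):
            raise SchemaError("values and status must share the member index")
        self.values = values
        self.status = status.copy()
        self.status.columns = [int(c) for c in self.status.columns]
        self.meta = dict(meta)
        self.emigration_absorbing = emigration_absorbing
        self.validate()

    # -- basic properties -------------------------------------------------
    @property
    def n_members(self) -> int:
        return len(self.values)

    @property
    def n_sweeps(self) -> int:
        return int(max(self.status.columns))

    @property
    def member_ids(self) -> pd.Index:
        return self.values.index

    def validate(self) -> None:
        unknown = set(self.values.columns) - set(self.meta)
        if unknown:
            raise SchemaError(
                "variables present in data but absent from metadata: "
                + ", ".join(sorted(unknown))
            )
        for name, m in self.meta.items():
            if m.origin_sweep > self.n_sweeps:
                raise SchemaError(
                    f"variable {name!r}: origin_sweep {m.origin_sweep} "
                    f"beyond last sweep {self.n_sweeps}"
                )
        arr = self.status.to_numpy(dtype=object)
        bad = ~np.isin(arr, list(_STATUS_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise SchemaError(
                f"illegal status code {arr[i, j]!r} for member "
                f"{self.status.index[i]!r} at sweep {self.status.columns[j]}"
            )
        self._check_absorbing(arr, DEAD, "death")
        if self.emigration_absorbing:
            self._check_absorbing(arr, EMIGRATED, "emigration")

    def _check_absorbing(self, arr: np.ndarray, code: str, label: str) -> None:
        hit = arr == code
        if not hit.any():
            return
        first = np.where(hit.any(axis=1), hit.argmax(axis=1), arr.shape[1])
        cols = np.arange(arr.shape[1])
        offender = (cols[None, :] > first[:, None]) & ~hit
        # a member who entered the absorbing state must stay in it
        offender &= hit.any(axis=1)[:, None]
        if offender.any():
            i, j = np.argwhere(offender)[0]
            raise ConsistencyError(
                f"non-absorbing {label}: member {self.status.index[i]!r} is "
                f"{arr[i, j]!r} at sweep {self.status.columns[j]} after "
                f"{label} at sweep {self.status.columns[int(first[i])]}"
            )

    # -- eligibility and non-response ------------------------------------
    def eligible(self, sweep: int) -> pd.Series:
        """Boolean mask of members alive and not emigrated at ``sweep``."""
        self._check_sweep(sweep, low=1)
        return self.status[sweep].isin([RESPONDENT, NONRESPONDENT])

    def _check_sweep(self, sweep: int, low: int) -> None:
        if not (low <= sweep <= self.n_sweeps):
            raise ValueError(
                f"sweep must be in {low}..{self.n_sweeps}, got {sweep}"
            )

    def sweep_frame(self, sweep: int) -> SweepFrame:
        col = self.status[sweep]
        return SweepFrame(
            sweep=sweep,
            eligible_n=int(col.isin([RESPONDENT, NONRESPONDENT]).sum()),
            respondents_n=int((col == RESPONDENT).sum()),
            nonrespondents_n=int((col == NONRESPONDENT).sum()),
        )

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.values.copy(),
            self.status.copy(),
            dict(self.meta),
            emigration_absorbing=self.emigration_absorbing,
        )


def derive_nonresponse(
    cohort: CohortTable, sweep: int
) -> tuple[SweepFrame, pd.Series]:
    """Non-response indicator at ``sweep`` over the eligible sample.

    Returns the per-sweep accounting frame and a float series that is 1 for
    non-respondents, 0 for respondents, and ``NaN`` for members excluded as
    dead or emigrated (non-response is undefined for them).
    """
    cohort._check_sweep(sweep, low=2)
    col = cohort.status[sweep]
    ind = pd.Series(np.nan, index=cohort.member_ids, name=f"nonresponse_{sweep}")
    ind[col == NONRESPONDENT] = 1.0
    ind[col == RESPONDENT] = 0.0
    return cohort.sweep_frame(sweep), ind


def prior_participation(cohort: CohortTable, sweep: int) -> pd.Series:
    """Incomplete-response indicator over sweeps ``1..sweep-1``.

    1 when the member missed (was a non-respondent at) any earlier sweep
    while eligible, 0 when they responded at every earlier sweep at which
    they were eligible.  ``NaN`` for members not eligible at the target
    sweep, for whom the analysis is undefined.
    """
    cohort._check_sweep(sweep, low=2)
    earlier = cohort.status[[s for s in cohort.status.columns if s < sweep]]
    missed = (earlier == NONRESPONDENT).any(axis=1).astype(float)
    missed[~cohort.eligible(sweep)] = np.nan
    missed.name = f"prior_incomplete_{sweep}"
    return missed


def participation_summary(cohort: CohortTable) -> pd.DataFrame:
    """Per-sweep accounting table: total, dead, emigrated, eligible, counts."""
    rows = []
    total = cohort.n_members
    for s in sorted(cohort.status.columns):
        col = cohort.status[s]
        dead = int((col == DEAD).sum())
        emig = int((col == EMIGRATED).sum())
        rows.append(
            {
                "sweep": s,
                "total": total,
                "dead": dead,
                "emigrated": emig,
                "eligible": total - dead - emig,
                "respondents": int((col == RESPONDENT).sum()),
                "nonrespondents": int((col == NONRESPONDENT).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("sweep")


# -- text I/O -------------------------------------------------------------

_STATUS_PREFIX = "status_sweep"


def _meta_to_frame(meta: Mapping[str, VariableMeta]) -> pd.DataFrame:
    rows = []
    for m in meta.values():
        rows.append(
            {
                "name": m.name,
                "origin_sweep": m.origin_sweep,
                "var_type": m.var_type,
                "routed": int(m.routed),
                "composite_of": ";".join(m.composite_of or ()),
                "category_labels": ";".join(m.category_labels or ()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "origin_sweep",
            "var_type",
            "routed",
            "composite_of",
            "category_labels",
        ],
    )


def _meta_from_frame(df: pd.DataFrame) -> dict[str, VariableMeta]:
    meta: dict[str, VariableMeta] = {}
    for _, row in df.iterrows():
        comp = str(row.get("composite_of") or "")
        labels = str(row.get("category_labels") or "")
        meta[str(row["name"])] = VariableMeta(
            name=str(row["name"]),
            origin_sweep=int(row["origin_sweep"]),
            var_type=str(row["var_type"]),
            routed=bool(int(row["routed"])) if str(row["routed"]) != "" else False,
            composite_of=tuple(comp.split(";")) if comp else None,
            category_labels=tuple(labels.split(";")) if labels else None,
        )
    return meta


def write_cohort(
    cohort: CohortTable, table_path: str | Path, meta_path: str | Path
) -> None:
    """Write the cohort and its metadata as delimited text.

    One row per member; value columns first, then one ``status_sweep<k>``
    column per sweep holding the codes R/N/D/E.  Missing values are written
    as empty cells.
    """
    out = cohort.values.copy()
    for s in sorted(cohort.status.columns):
        out[f"{_STATUS_PREFIX}{s}"] = cohort.status[s]
    out.to_csv(table_path, index_label="member_id")
    _meta_to_frame(cohort.meta).to_csv(meta_path, index=False)


def read_cohort(
    table_path: str | Path,
    meta_path: str | Path,
    missing: str = "",
    emigration_absorbing: bool = True,
) -> CohortTable:
    """Read a cohort written by :func:`write_cohort` (or hand-built text).

    ``missing`` is the sentinel string standing for a missing value in the
    table; it is converted to an explicit NaN/None mask on read.  All cohort
    invariants are checked; violations raise :class:`SchemaError` or
    :class:`ConsistencyError`.
    """
    na_vals = [missing] if missing else [""]
    raw = pd.read_csv(
        table_path,
        index_col="member_id",
        na_values=na_vals,
        keep_default_na=False,
        dtype=str,
    )
    meta = _meta_from_frame(
        pd.read_csv(meta_path, na_values=[""], keep_default_na=False, dtype=str)
    )
    status_cols = [c for c in raw.columns if c.startswith(_STATUS_PREFIX)]
    if not status_cols:
        raise SchemaError("no status_sweep<k> columns found")
    status = raw[status_cols].copy()
    status.columns = [int(c[len(_STATUS_PREFIX):]) for c in status_cols]
    values = raw.drop(columns=status_cols)
    for name in values.columns:
        if name not in meta:
            raise SchemaError(f"variable {name!r} present in data but not in metadata")
        if meta[name].var_type in ("continuous", "binary", "ordinal"):
            # astype uses the correctly rounded parser, so shortest-repr
            # floats written by to_csv round-trip bit-exactly
            values[name] = values[name].astype(float)
        else:
            values[name] = values[name].astype(object).where(values[name].notna(), np.nan)
    return CohortTable(
        values, status, meta, emigration_absorbing=emigration_absorbing
    )
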