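"""Design-matrix construction for regression models.

Continuous, binary and ordinal variables enter as single numeric columns;
categorical variables expand to reference-coded indicator columns named
``var[level]``, the reference being the first entry of the variable's
``category_labels`` (or the first observed level when labels are absent).
This mirrors the reference groups of risk-ratio tables where the most
disadvantaged category is listed first as "Ref".
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import VariableMeta
from .errors import SchemaError


def term_columns(name: str, meta: Mapping[str, VariableMeta]) -> list[str]:
    """Design column names a variable expands to."""
    m = meta[name]
    if m.var_type == "categorical":
        levels = _levels(m)
        return [f"{name}[{lv}]" for lv in levels[1:]]
    return [name]


def _levels(m: VariableMeta) -> list[str]:
    if m.category_labels:
        return list(m.category_labels)
    raise SchemaError(
        f"categorical variable {m.name!r} needs category_labels to define "
        "its reference level"
    )


def build_design(
    data: pd.DataFrame,
    terms: Sequence[str],
    meta: Mapping[str, VariableMeta],
    add_intercept: bool = True,
) -> pd.DataFrame:
    """Expand ``terms`` of ``data`` into a numeric design matrix.

    Rows with missing values are preserved as NaN rows (complete-case
    dropping is the fitting routine's responsibility).  Categorical columns
    always produce the same indicator columns regardless of which levels
    happen to be present, so designs are comparable across imputed datasets.
    """
    cols: dict[str, np.ndarray] = {}
    if add_intercept:
        cols["const"] = np.ones(len(data))
    for name in terms:
        if name not in meta:
            raise SchemaError(f"no metadata for term {name!r}")
        m = meta[name]
        s = data[name]
        if m.var_type == "categorical":
            levels = _levels(m)
            known = s.dropna().unique()
            stray = set(known) - set(levels)
            if stray:
                raise SchemaError(
                    f"variable {name!r}: values {sorted(stray)} not in "
                    "category_labels"
                )
            isna = s.isna().to_numpy()
            for lv in levels[1:]:
                col = (s == lv).to_numpy(dtype=float)
                col[isna] = np.nan
                cols[f"{name}[{lv}]"] = col
        else:
            cols[name] = pd.to_numeric(s, errors="raise").to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)
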