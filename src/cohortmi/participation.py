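"""Published BCS70 participation counts and their arithmetic.

The 1970 British Cohort Study reports, for each of its ten sweeps (birth to
age 46), the total cohort, deaths, emigrations and respondent counts.  The
eligible sample at a sweep is the total minus deaths and emigrations — the
cohort members still alive and resident, who form the target population for
non-response analyses.  This module ships those printed counts as package
data and recomputes the derived quantities (eligible sample, non-response
percentages) from them, which also serves as an arithmetic check of the
cohort-accounting layer.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import SweepFrame


def published_participation() -> pd.DataFrame:
    """The published per-sweep participation counts, indexed by sweep."""
    with resources.files("cohortmi.data").joinpath("bcs70_table1.csv").open() as fh:
        df = pd.read_csv(fh)
    return df.set_index("sweep")


def recompute_frames(counts: pd.DataFrame) -> dict[int, SweepFrame]:
    """Rebuild :class:`SweepFrame` accounting from printed raw counts.

    Only ``total``, ``dead``, ``emigrated`` and ``respondents`` are used;
    eligible and non-respondent counts are derived, so comparing them with
    the printed columns exercises the accounting identities.
    """
    frames = {}
    for sweep, row in counts.iterrows():
        frames[int(sweep)] = SweepFrame.from_counts(
            sweep=int(sweep),
            total=int(row["total"]),
            dead=int(row["dead"]),
            emigrated=int(row["emigrated"]),
            respondents=int(row["respondents"]),
        )
    return frames
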