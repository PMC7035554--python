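"""Schedule-derived covariates.

Three nonclinical covariates are derived from the realized schedule:

* ``surgeon_daily_n`` — how many surgeries this record's surgeon performed
  on this date (the surgeon's daily workload);
* ``or_daily_n`` — how many surgeries were performed in this record's
  operating room on this date (the OR's daily workload);
* ``position_label`` — the string ``"k~j"``: this is the j-th surgery of a
  day on which its surgeon performs k surgeries.  ``"1~1"`` (a surgeon's
  only case of the day) is the reference category.

Ordering within a surgeon-day is by cut time on the rollover-resolved
timeline, with ties broken by wheel-in time and then record id so the
ordering is total and deterministic.  By construction ``surgeon_daily_n``
is the ``k`` of ``position_label`` — the two are exactly collinear, which
is why the regression models use one or the other, never both.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .ingest import DurationRecord, records_to_frame

#: positions beyond this caseload are structurally allowed but flagged
MAX_TYPICAL_CASELOAD = 5

FEATURE_COLUMNS = ("surgeon_daily_n", "or_daily_n", "position_rank", "position_label")


def derive_features(records: "pd.DataFrame | Iterable[DurationRecord]") -> pd.DataFrame:
    """Annotate each record with workload and position covariates.

    Accepts either a frame from :func:`orduration.ingest.records_to_frame`
    or an iterable of :class:`DurationRecord`.  Returns a copy with the
    columns in :data:`FEATURE_COLUMNS` added; row order of the input is
    preserved.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if df.empty:
        out = df.copy()
        for c in FEATURE_COLUMNS:
            out[c] = pd.Series(dtype=object if c == "position_label" else int)
        return out
    df = df.copy()
    order = df.sort_values(
        ["surgeon", "date", "cut_min", "enter_min", "record_id"], kind="mergesort"
    )
    grp = order.groupby(["surgeon", "date"], sort=False)
    rank = grp.cumcount() + 1
    size = grp["record_id"].transform("size")
    df["surgeon_daily_n"] = size.reindex(df.index)
    df["position_rank"] = rank.reindex(df.index)
    df["or_daily_n"] = df.groupby(["or_id", "date"])["record_id"].transform("size")
    df["position_label"] = (
        df["surgeon_daily_n"].astype(str) + "~" + df["position_rank"].astype(str)
    )
    n_heavy = int((df["surgeon_daily_n"] > MAX_TYPICAL_CASELOAD).sum())
    if n_heavy:
        import logging

        logging.getLogger(__name__).warning(
            "%d records with surgeon daily caseload above %d (positions beyond "
            "'%d~%d' are unusual)",
            n_heavy,
            MAX_TYPICAL_CASELOAD,
            MAX_TYPICAL_CASELOAD,
            MAX_TYPICAL_CASELOAD,
        )
    return df


def workload_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Frequency table of workloads and position labels.

    One row per level of each of: surgeon daily caseload, position label,
    and OR daily workload; columns ``kind``, ``level``, ``n``,
    ``percent`` (percent of all records).  Within each ``kind`` the
    percentages sum to 100 up to rounding.  Empty input yields an empty
    table.
    """
    cols = ["kind", "level", "n", "percent"]
    if rows.empty:
        return pd.DataFrame(columns=cols)
    total = len(rows)
    parts = []
    for kind, col in (
        ("surgeon_caseload", "surgeon_daily_n"),
        ("position", "position_label"),
        ("or_load", "or_daily_n"),
    ):
        counts = rows[col].value_counts().sort_index()
        parts.append(
            pd.DataFrame(
                {
                    "kind": kind,
                    "level": counts.index.astype(str),
                    "n": counts.to_numpy(),
                    "percent": counts.to_numpy() / total * 100.0,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)[cols]


def caseload_percentages(rows: pd.DataFrame) -> pd.Series:
    """Percent of records whose surgeon performed k surgeries that day,
    indexed by k (the 'k surgeries in a day' column of the main report)."""
    s = rows["surgeon_daily_n"].value_counts(normalize=True).sort_index() * 100.0
    s.index.name = "surgeon_daily_n"
    s.name = "percent"
    return s
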