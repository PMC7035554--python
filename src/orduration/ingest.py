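"""Reading, validating and normalising operation-level schedule records.

A record is one surgery: patient identifiers, categorical attributes
(surgeon, operating room, surgery type, anaesthetist, weekday) and five
clock times on a calendar date::

    wheel-in -> anaesthesia -> first cut -> last suture -> wheel-out

The analysis outcome is the cut-to-suture interval in minutes, modelled on
the natural-log scale.  Clock times are kept at minute resolution; a
surgery whose suture time clock-precedes its cut time is taken to have
crossed midnight (the date is the admission date, not a per-timestamp
date), so 24 h is added for every backwards step on the within-day
timeline.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
import logging
import math
import re
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

WEEKDAYS = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun")

#: canonical column names, in canonical output order
CANONICAL_COLUMNS = (
    "record_id",
    "sex",
    "age",
    "date",
    "weekday",
    "or_id",
    "surgeon",
    "surgery_type",
    "anaesthetist",
    "t_enter",
    "t_anaesthesia",
    "t_cut",
    "t_sew",
    "t_leave",
)

TIME_FIELDS = ("t_enter", "t_anaesthesia", "t_cut", "t_sew", "t_leave")

#: weekday column is optional on input (it is recomputed from the date)
OPTIONAL_COLUMNS = frozenset({"weekday"})

MINUTES_PER_DAY = 1440


class SchemaError(ValueError):
    """The input table is missing a required column (or the mapping is bad)."""


class ValidationError(ValueError):
    """A record violates a dataset invariant."""


@dataclass(frozen=True)
class RowError:
    """A row-level parse/validation failure, reported with its source row."""

    row: int  # 1-based data-row number (header excluded)
    record_id: str | None
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        rid = f" (id={self.record_id})" if self.record_id else ""
        return f"row {self.row}{rid}: {self.message}"


@dataclass(frozen=True)
class SurgeryRecord:
    """One operation with identifiers, attributes and five clock times."""

    record_id: str
    sex: str
    age: int
    date: dt.date
    or_id: str
    surgeon: str
    surgery_type: str
    anaesthetist: str
    t_enter: dt.time
    t_anaesthesia: dt.time
    t_cut: dt.time
    t_sew: dt.time
    t_leave: dt.time

    @property
    def weekday(self) -> str:
        return WEEKDAYS[self.date.weekday()]

    def timeline_minutes(self) -> tuple[int, int, int, int, int]:
        """Absolute minutes of the five time points on the within-day
        timeline, adding 24 h at every backwards clock step (midnight
        rollover)."""
        clocks = [getattr(self, f) for f in TIME_FIELDS]
        out: list[int] = []
        offset = 0
        prev = None
        for t in clocks:
            m = t.hour * 60 + t.minute + offset
            if prev is not None and m < prev:
                offset += MINUTES_PER_DAY
                m += MINUTES_PER_DAY
            out.append(m)
            prev = m
        return tuple(out)  # type: ignore[return-value]

    def validate(self) -> None:
        if self.age < 0:
            raise ValidationError(f"age must be >= 0, got {self.age}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        tl = self.timeline_minutes()
        # rollover resolution makes every backwards clock step a midnight
        # crossing, so a mis-ordered timeline shows up as a stay that is
        # implausibly long rather than as a non-monotone sequence
        if tl[-1] - tl[0] > MINUTES_PER_DAY:
            raise ValidationError(
                "timeline spans more than 24 h after midnight-rollover "
                f"resolution; times are not consistently ordered: {tl}"
            )


@dataclass(frozen=True)
class DurationRecord:
    """A validated record plus the outcome: cut-to-suture minutes and its
    natural log."""

    record: SurgeryRecord
    duration_min: float
    log_duration: float

    def __getattr__(self, name):  # delegate plain fields to the record
        return getattr(self.record, name)


@dataclass
class IngestResult(Sequence):
    """Parsed records plus the row-level failure report.

    Behaves as a sequence of the successfully parsed records; failures are
    available in :attr:`errors`.
    """

    records: list[SurgeryRecord]
    errors: list[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def __iter__(self) -> Iterator[SurgeryRecord]:
        return iter(self.records)


def _parse_time(text: str) -> dt.time:
    # tolerate "11 : 15" spacing seen in printed schedules
    s = re.sub(r"\s*:\s*", ":", str(text).strip())
    m = re.fullmatch(r"(\d{1,2}):(\d{2})", s)
    if not m:
        raise ValueError(f"unparsable time {text!r} (expected HH:MM)")
    hh, mm = int(m.group(1)), int(m.group(2))
    if not (0 <= hh <= 23 and 0 <= mm <= 59):
        raise ValueError(f"time out of range: {text!r}")
    return dt.time(hh, mm)


def _parse_date(text: str, dayfirst: bool) -> dt.date:
    s = str(text).strip()
    m = re.fullmatch(r"(\d{4})-(\d{1,2})-(\d{1,2})", s)
    if m:
        return dt.date(int(m.group(1)), int(m.group(2)), int(m.group(3)))
    m = re.fullmatch(r"(\d{1,2})/(\d{1,2})/(\d{4})", s)
    if m:
        a, b, y = int(m.group(1)), int(m.group(2)), int(m.group(3))
        d, mo = (a, b) if dayfirst else (b, a)
        return dt.date(y, mo, d)
    raise ValueError(f"unparsable date {text!r} (expected ISO or d/m/Y)")


def load_schema(schema: Mapping[str, str] | str | Path | None) -> dict[str, str]:
    """Resolve a column-name mapping (canonical -> actual header).

    Accepts a mapping, a YAML/JSON file path, or None (identity mapping).
    """
    if schema is None:
        return {c: c for c in CANONICAL_COLUMNS}
    if isinstance(schema, (str, Path)):
        text = Path(schema).read_text()
        loaded = yaml.safe_load(text) if not str(schema).endswith(".json") else json.loads(text)
        schema = loaded
    out = {c: c for c in CANONICAL_COLUMNS}
    for canon, actual in dict(schema).items():
        if canon not in CANONICAL_COLUMNS:
            raise SchemaError(f"unknown canonical column {canon!r} in schema config")
        out[canon] = actual
    return out


def read_records(
    path: str | Path,
    schema_config: Mapping[str, str] | str | Path | None = None,
    *,
    dayfirst: bool = True,
    delimiter: str = ",",
    weekday_policy: str = "strict",
) -> IngestResult:
    """Read schedule records from a delimited text file.

    Parameters
    ----------
    path
        CSV file, UTF-8, one header row.
    schema_config
        Mapping from canonical column names to the file's actual headers
        (or a YAML/JSON file containing one).  Unmapped columns default to
        their canonical names.
    dayfirst
        Dialect of slashed dates: ``6/1/2016`` is 6 January when True
        (default), 1 June when False.  ISO dates are always accepted.
    weekday_policy
        What to do when an input weekday column disagrees with the weekday
        computed from the date: ``"strict"`` (row-level validation error,
        the default), ``"warn"`` (log and keep the row) or ``"ignore"``.

    Returns
    -------
    IngestResult
        Sequence of valid :class:`SurgeryRecord`; rows that fail to parse
        or validate are collected in ``.errors`` with their row numbers.

    Raises
    ------
    SchemaError
        If a required column is absent from the header.
    """
    if weekday_policy not in ("strict", "warn", "ignore"):
        raise ValueError(f"unknown weekday_policy {weekday_policy!r}")
    colmap = load_schema(schema_config)
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for canon in CANONICAL_COLUMNS:
            if canon in OPTIONAL_COLUMNS:
                continue
            if colmap[canon] not in header:
                raise SchemaError(
                    f"required column {colmap[canon]!r} (canonical {canon!r}) "
                    f"missing from header {header}"
                )
        has_weekday = colmap["weekday"] in header

        records: list[SurgeryRecord] = []
        errors: list[RowError] = []
        seen_ids: dict[str, int] = {}
        for i, row in enumerate(reader, start=1):
            rid = (row.get(colmap["record_id"]) or "").strip() or None
            try:
                rec = _parse_row(row, colmap, dayfirst)
                rec.validate()
                if rec.record_id in seen_ids:
                    raise ValidationError(
                        f"duplicate record_id {rec.record_id!r} "
                        f"(first seen at row {seen_ids[rec.record_id]})"
                    )
                if has_weekday:
                    given = (row.get(colmap["weekday"]) or "").strip()[:3].title()
                    if given and given != rec.weekday:
                        msg = (
                            f"weekday {given!r} disagrees with date "
                            f"{rec.date.isoformat()} ({rec.weekday})"
                        )
                        if weekday_policy == "strict":
                            raise ValidationError(msg)
                        if weekday_policy == "warn":
                            log.warning("row %d: %s", i, msg)
                seen_ids[rec.record_id] = i
                records.append(rec)
            except (ValueError, KeyError) as exc:
                errors.append(RowError(row=i, record_id=rid, message=str(exc)))
    if errors:
        log.info("read_records: %d rows excluded by validation", len(errors))
    return IngestResult(records=records, errors=errors)


def _parse_row(row: Mapping[str, str], colmap: Mapping[str, str], dayfirst: bool) -> SurgeryRecord:
    def get(canon: str) -> str:
        v = row.get(colmap[canon])
        if v is None or str(v).strip() == "":
            raise ValueError(f"missing value for column {colmap[canon]!r}")
        return str(v).strip()

    times = {f: _parse_time(get(f)) for f in TIME_FIELDS}
    return SurgeryRecord(
        record_id=get("record_id"),
        sex=get("sex").upper(),
        age=int(get("age")),
        date=_parse_date(get("date"), dayfirst),
        or_id=get("or_id"),
        surgeon=get("surgeon"),
        surgery_type=get("surgery_type"),
        anaesthetist=get("anaesthetist"),
        **times,
    )


DEFAULT_DURATION_CAP_MIN = 24 * 60  # plausibility cap on one operation


def compute_duration(
    rec: SurgeryRecord, *, cap_minutes: float = DEFAULT_DURATION_CAP_MIN
) -> DurationRecord:
    """Attach the outcome: cut-to-suture minutes and its natural log.

    Midnight rollover is already resolved by the record's within-day
    timeline, so the duration is simply the difference of the resolved cut
    and suture minutes.
    """
    tl = rec.timeline_minutes()
    duration = float(tl[3] - tl[2])
    if duration <= 0:
        raise ValidationError(
            f"record {rec.record_id}: nonpositive cut-to-suture duration {duration}"
        )
    if duration > cap_minutes:
        raise ValidationError(
            f"record {rec.record_id}: duration {duration:.0f} min exceeds "
            f"plausibility cap {cap_minutes:.0f} min (outlier)"
        )
    return DurationRecord(record=rec, duration_min=duration, log_duration=math.log(duration))


def compute_durations(
    records: Iterable[SurgeryRecord], *, cap_minutes: float = DEFAULT_DURATION_CAP_MIN
) -> tuple[list[DurationRecord], list[RowError]]:
    """Vector form of :func:`compute_duration`; failures are collected, not
    raised."""
    out: list[DurationRecord] = []
    errs: list[RowError] = []
    for i, rec in enumerate(records, start=1):
        try:
            out.append(compute_duration(rec, cap_minutes=cap_minutes))
        except ValidationError as exc:
            errs.append(RowError(row=i, record_id=rec.record_id, message=str(exc)))
    return out, errs


def write_records(records: Iterable[SurgeryRecord], path: str | Path) -> None:
    """Write records as canonical CSV (ISO dates, HH:MM times)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CANONICAL_COLUMNS)
        for rec in records:
            rec = getattr(rec, "record", rec)  # accept DurationRecord too
            w.writerow(
                [
                    rec.record_id,
                    rec.sex,
                    rec.age,
                    rec.date.isoformat(),
                    rec.weekday,
                    rec.or_id,
                    rec.surgeon,
                    rec.surgery_type,
                    rec.anaesthetist,
                ]
                + [getattr(rec, f).strftime("%H:%M") for f in TIME_FIELDS]
            )


def records_to_frame(records: Iterable[DurationRecord | SurgeryRecord]) -> pd.DataFrame:
    """Tabulate records (with outcome columns when present) for the feature
    and modelling stages."""
    rows = []
    for r in records:
        rec = getattr(r, "record", r)
        tl = rec.timeline_minutes()
        d = {
            "record_id": rec.record_id,
            "sex": rec.sex,
            "age": rec.age,
            "date": rec.date,
            "weekday": rec.weekday,
            "or_id": rec.or_id,
            "surgeon": rec.surgeon,
            "surgery_type": rec.surgery_type,
            "anaesthetist": rec.anaesthetist,
            "enter_min": tl[0],
            "cut_min": tl[2],
        }
        for f, m in zip(TIME_FIELDS, tl):
            d[f] = getattr(rec, f).strftime("%H:%M")
        if isinstance(r, DurationRecord):
            d["duration_min"] = r.duration_min
            d["log_duration"] = r.log_duration
        rows.append(d)
    return pd.DataFrame(rows)


def load_frame(
    path: str | Path,
    schema_config: Mapping[str, str] | str | Path | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, list[RowError]]:
    """Convenience: read, validate, compute outcomes and tabulate."""
    res = read_records(path, schema_config, **kwargs)
    durs, errs = compute_durations(res.records)
    return records_to_frame(durs), res.errors + errs
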