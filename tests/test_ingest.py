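"""Record parsing, validation and the cut-to-suture outcome."""

import datetime as dt
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orduration import (
    SchemaError,
    SurgeryRecord,
    ValidationError,
    compute_duration,
    read_records,
    records_to_frame,
    write_records,
)
from orduration.ingest import compute_durations

from conftest import TABLE1_HEADER, TABLE1_ROWS, TABLE1_SCHEMA


def _rec(t_cut="12:00", t_sew="13:00", **kw):
    times = dict(t_enter="11:00", t_anaesthesia="11:30", t_cut=t_cut, t_sew=t_sew)
    times["t_leave"] = kw.pop("t_leave", t_sew)
    for f in ("t_enter", "t_anaesthesia"):
        if f in kw:
            times[f] = kw.pop(f)
    defaults = dict(
        record_id="r1",
        sex="F",
        age=50,
        date=dt.date(2016, 1, 6),
        or_id="OR1",
        surgeon="A",
        surgery_type="T1",
        anaesthetist="X",
    )
    defaults.update(kw)
    parsed = {k: dt.time(*map(int, v.split(":"))) for k, v in times.items()}
    return SurgeryRecord(**defaults, **parsed)


class TestReadRecords:
    def test_printed_sample_rows_parse_with_correct_durations(self, table1_csv):
        res = read_records(table1_csv, TABLE1_SCHEMA, weekday_policy="warn")
        assert len(res) == 3 and not res.errors
        durs, errs = compute_durations(res.records)
        assert not errs
        assert [d.duration_min for d in durs] == [67.0, 97.0, 92.0]
        # day-first dialect: 6/1/2016 is 6 January 2016
        assert res[0].date == dt.date(2016, 1, 6)

    def test_printed_weekday_column_is_inconsistent_with_dates(self, table1_csv):
        # the sample table's Day column is one weekday ahead of its dates,
        # so strict validation rejects every row (documented discrepancy)
        res = read_records(table1_csv, TABLE1_SCHEMA, weekday_policy="strict")
        assert len(res) == 0 and len(res.errors) == 3
        assert all("weekday" in e.message for e in res.errors)

    def test_header_only_file_yields_empty_list_without_errors(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(TABLE1_HEADER + "\n")
        res = read_records(p, TABLE1_SCHEMA)
        assert len(res) == 0 and res.errors == []

    def test_malformed_time_excludes_only_that_row(self, tmp_path):
        bad = TABLE1_ROWS[1].replace("13:43", "25:61")
        p = tmp_path / "bad.csv"
        p.write_text(TABLE1_HEADER + "\n" + TABLE1_ROWS[0] + "\n" + bad + "\n")
        res = read_records(p, TABLE1_SCHEMA, weekday_policy="ignore")
        assert len(res) == 1 and res[0].record_id == "6952 x 5"
        assert len(res.errors) == 1 and res.errors[0].row == 2

    def test_duplicate_record_id_is_a_row_error(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text(TABLE1_HEADER + "\n" + TABLE1_ROWS[0] + "\n" + TABLE1_ROWS[0] + "\n")
        res = read_records(p, TABLE1_SCHEMA, weekday_policy="ignore")
        assert len(res) == 1
        assert len(res.errors) == 1 and "duplicate" in res.errors[0].message

    def test_missing_column_raises_schema_error_naming_it(self, tmp_path):
        p = tmp_path / "noor.csv"
        header = TABLE1_HEADER.replace("OR,", "Theatre,")
        p.write_text(header + "\n")
        with pytest.raises(SchemaError, match="OR"):
            read_records(p, TABLE1_SCHEMA)

    def test_monthfirst_dialect_flag(self, tmp_path):
        p = tmp_path / "us.csv"
        p.write_text(TABLE1_HEADER + "\n" + TABLE1_ROWS[0] + "\n")
        res = read_records(p, TABLE1_SCHEMA, dayfirst=False, weekday_policy="ignore")
        assert res[0].date == dt.date(2016, 6, 1)


class TestComputeDuration:
    @pytest.mark.parametrize(
        "t_cut,t_sew,expect",
        [
            ("12:18", "13:25", 67.0),
            ("13:43", "15:20", 97.0),
            ("23:30", "00:40", 70.0),  # midnight rollover
        ],
    )
    def test_duration_minutes(self, t_cut, t_sew, expect):
        d = compute_duration(_rec(t_cut=t_cut, t_sew=t_sew))
        assert d.duration_min == expect
        assert d.log_duration == pytest.approx(math.log(expect))

    def test_log_back_transform_identity(self):
        d = compute_duration(_rec())
        assert math.exp(d.log_duration) == pytest.approx(d.duration_min)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValidationError, match="nonpositive"):
            compute_duration(_rec(t_cut="12:00", t_sew="12:00"))

    def test_cap_flags_outliers(self):
        with pytest.raises(ValidationError, match="cap"):
            compute_duration(_rec(t_cut="12:00", t_sew="14:00"), cap_minutes=60)

    @settings(deadline=None, derandomize=True)
    @given(start=st.integers(0, 1439), k=st.integers(1, 600))
    def test_duration_increases_linearly_with_suture_time(self, start, k):
        # moving the suture k minutes later adds exactly k minutes
        def mk(sew_minutes):
            sew = f"{(sew_minutes // 60) % 24:02d}:{sew_minutes % 60:02d}"
            cut = f"{start // 60:02d}:{start % 60:02d}"
            return compute_duration(
                _rec(
                    t_enter="00:00",
                    t_anaesthesia="00:00",
                    t_cut=cut,
                    t_sew=sew,
                    t_leave=sew,
                )
            ).duration_min

        assert mk(start + k + 1) - mk(start + k) == 1.0

    def test_timeline_order_enforced(self):
        r = _rec(t_cut="10:00", t_sew="13:00")  # cut before anaesthesia
        with pytest.raises(ValidationError, match="timeline"):
            r.validate()


class TestRoundTrip:
    def test_write_then_read_reproduces_records(self, table1_csv, tmp_path):
        res = read_records(table1_csv, TABLE1_SCHEMA, weekday_policy="warn")
        out = tmp_path / "canon.csv"
        write_records(res.records, out)
        back = read_records(out)  # canonical names, ISO dates
        assert back.errors == []
        assert back.records == res.records
        # and the normalized tables agree field for field
        f1 = records_to_frame(res.records)
        f2 = records_to_frame(back.records)
        assert f1.equals(f2)
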