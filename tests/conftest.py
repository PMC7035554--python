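import pytest

from orduration import SyntheticConfig, generate_frame

# Three printed sample records (slashed dates are day-first).  The Day
# column as printed is internally inconsistent with the dates: each
# printed weekday is one day ahead of the weekday the date falls on, so
# strict weekday validation rejects these rows and tests that only need
# the timestamps parse with weekday_policy="warn".
TABLE1_HEADER = (
    "ID,Sex,Age,Date,Day,OR,Surgeon,Surgery type,Anaesthetist,"
    "Enter time,Anaesthesia time,Cut time,Sew time,Leave time"
)
TABLE1_ROWS = [
    "6952 x 5,F,46,6/1/2016,Thu,OR10,A,Surgery 11,A,11:15,11:29,12:18,13:25,13:40",
    "69 x 504,F,29,7/1/2016,Fri,OR02,A,Surgery 4,B,13:06,13:21,13:43,15:20,15:30",
    "69 x 541,M,57,8/1/2016,Sat,OR15,A,Surgery 4,C,10:54,11:56,12:28,14:00,14:10",
]
TABLE1_SCHEMA = {
    "record_id": "ID",
    "sex": "Sex",
    "age": "Age",
    "date": "Date",
    "weekday": "Day",
    "or_id": "OR",
    "surgeon": "Surgeon",
    "surgery_type": "Surgery type",
    "anaesthetist": "Anaesthetist",
    "t_enter": "Enter time",
    "t_anaesthesia": "Anaesthesia time",
    "t_cut": "Cut time",
    "t_sew": "Sew time",
    "t_leave": "Leave time",
}


@pytest.fixture
def table1_csv(tmp_path):
    p = tmp_path / "sample.csv"
    p.write_text(TABLE1_HEADER + "\n" + "\n".join(TABLE1_ROWS) + "\n")
    return p


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def default_frame(default_cfg):
    """The default synthetic dataset (seed 7, ~2451 rows), feature-ready.

    Session-scoped and treated as read-only by every test that uses it.
    """
    df, truth = generate_frame(default_cfg)
    return df, truth
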