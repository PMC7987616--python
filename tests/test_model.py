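import datetime as dt

import pytest

from ehrcohort import load_database, write_database
from ehrcohort.dates import add_years, age_in_years, last_day_at_age, parse_date
from ehrcohort.model import CodedEvent


def _write(tmp_path, practice, patient, events):
    (tmp_path / "practice.csv").write_text(practice)
    (tmp_path / "patient.csv").write_text(patient)
    (tmp_path / "events.csv").write_text(events)
    return tmp_path


GOOD_PRACTICE = "practice_id,key_date,collection_date\npr1,1998-01-01,2018-01-01\npr2,2000-05-05,2019-06-30\n"
GOOD_PATIENT = (
    "patient_id,practice_id,sex,birth_date,birth_precision,registration_date,"
    "deregistration_date,death_date,townsend_quintile,ethnicity\n"
    "a1,pr1,female,1950-02-03,day,1999-01-01,,,2,white\n"
    "a2,pr1,M,1960-07-08,day,2001-05-05,2010-01-01,,,\n"
    "a3,pr2,male,1955-01-01,year,2002-02-02,,2015-03-04,5,south_asian\n"
)
GOOD_EVENTS = (
    "patient_id,code,event_date,value,unit,table_of_origin\n"
    "a1,C10F.00,2005-01-01,,,clinical\n"
    "a1,BMI001,2006-06-06,27.3,kg/m2,measurement\n"
    "a2,MFN001,2004-04-04,,,therapy\n"
)


class TestLoad:
    def test_identity_load_counts(self, tmp_path):
        db = load_database(_write(tmp_path, GOOD_PRACTICE, GOOD_PATIENT, GOOD_EVENTS))
        assert len(db.practices) == 2
        assert db.n_patients == 3
        assert db.n_events == 3
        assert db.integrity.total == 0

    def test_sex_alias_and_year_precision_anchor(self, tmp_path):
        db = load_database(_write(tmp_path, GOOD_PRACTICE, GOOD_PATIENT, GOOD_EVENTS))
        assert db.patients["a2"].sex == "male"
        # year-precision birth anchored to July 1 by default
        assert db.patients["a3"].birth_date == dt.date(1955, 7, 1)
        db2 = load_database(tmp_path, year_birth_anchor=(1, 1))
        assert db2.patients["a3"].birth_date == dt.date(1955, 1, 1)

    def test_unknown_patient_event_dropped_and_counted(self, tmp_path):
        events = GOOD_EVENTS + "zz,C10F.00,2005-01-01,,,clinical\n"
        db = load_database(_write(tmp_path, GOOD_PRACTICE, GOOD_PATIENT, events))
        assert db.n_events == 3
        assert db.integrity.counts["event_unknown_patient"] == 1

    def test_inverted_patient_dates_rejected(self, tmp_path):
        patient = GOOD_PATIENT + "a4,pr1,female,1970-01-01,day,2005-01-01,2004-12-31,,,\n"
        db = load_database(_write(tmp_path, GOOD_PRACTICE, patient, GOOD_EVENTS))
        assert "a4" not in db.patients
        assert db.integrity.counts["patient_exit_before_registration"] == 1

    def test_duplicate_practice_is_fatal(self, tmp_path):
        practice = GOOD_PRACTICE + "pr1,1999-01-01,2017-01-01\n"
        with pytest.raises(ValueError, match="duplicate practice_id"):
            load_database(_write(tmp_path, practice, GOOD_PATIENT, GOOD_EVENTS))

    def test_missing_file_is_fatal(self, tmp_path):
        (tmp_path / "practice.csv").write_text(GOOD_PRACTICE)
        with pytest.raises(FileNotFoundError):
            load_database(tmp_path)

    def test_bad_date_drops_row(self, tmp_path):
        events = GOOD_EVENTS + "a1,C10F.00,not-a-date,,,clinical\n"
        db = load_database(_write(tmp_path, GOOD_PRACTICE, GOOD_PATIENT, events))
        assert db.n_events == 3
        assert db.integrity.counts["event_bad_date"] == 1


class TestRoundTrip:
    def test_load_write_load_identity(self, tmp_path, toy_db):
        out1 = tmp_path / "w1"
        out2 = tmp_path / "w2"
        write_database(toy_db, out1)
        db2 = load_database(out1)
        assert db2.practices == toy_db.practices
        assert db2.patients == toy_db.patients
        assert db2.events_by_patient == toy_db.events_by_patient
        # and the files themselves are reproduced byte-for-byte
        write_database(db2, out2)
        for name in ("practice.csv", "patient.csv", "events.csv"):
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes()


class TestEventsFor:
    def test_window_and_ordering(self, toy_db):
        evs = toy_db.events_for("pt001", {"C10F.00", "MFN001"},
                                (dt.date(2000, 1, 1), dt.date(2010, 1, 1)))
        assert [e.event_date for e in evs] == [dt.date(2005, 3, 1), dt.date(2007, 6, 15)]
        assert evs == sorted(evs, key=lambda e: e.sort_key())

    def test_empty_window_and_unknown_patient(self, toy_db):
        assert toy_db.events_for("pt001", {"C10F.00"},
                                 (dt.date(1990, 1, 1), dt.date(1991, 1, 1))) == []
        assert toy_db.events_for("nobody", {"C10F.00"},
                                 (dt.date(1990, 1, 1), dt.date(2020, 1, 1))) == []

    def test_same_day_ties_break_on_code(self):
        from ehrcohort.model import EHRDatabase, Practice, PatientRecord
        prac = {"p": Practice("p", dt.date(2000, 1, 1), dt.date(2010, 1, 1))}
        pats = {"x": PatientRecord("x", "p", "male", dt.date(1970, 1, 1), "day",
                                   dt.date(2000, 1, 1))}
        evs = [CodedEvent("x", "A1", dt.date(2005, 5, 5)),
               CodedEvent("x", "A0", dt.date(2005, 5, 5))]
        db = EHRDatabase(prac, pats, evs)
        got = db.events_for("x", {"A0", "A1"}, (dt.date(2005, 1, 1), dt.date(2005, 12, 31)))
        assert [e.code for e in got] == ["A0", "A1"]

    def test_matches_linear_scan_on_toy(self, toy_db):
        window = (dt.date(2004, 1, 1), dt.date(2009, 12, 31))
        codes = {"C10F.00", "C10F.11", "MFN001", "BMI001"}
        for pid in toy_db.patients:
            naive = sorted(
                (e for e in toy_db.events_of(pid)
                 if e.code in codes and window[0] <= e.event_date <= window[1]),
                key=lambda e: e.sort_key())
            assert toy_db.events_for(pid, codes, window) == naive


class TestDateArithmetic:
    @pytest.mark.parametrize("birth,years,expected", [
        ("1980-03-10", 25, "2005-03-10"),
        ("1920-02-29", 19, "1939-03-01"),   # leap birthday rolls forward
        ("1920-02-29", 20, "1940-02-29"),
    ])
    def test_add_years(self, birth, years, expected):
        assert add_years(dt.date.fromisoformat(birth), years) == dt.date.fromisoformat(expected)

    def test_completed_years_and_last_day_at_age(self):
        b = dt.date(1950, 6, 15)
        assert age_in_years(b, dt.date(2000, 6, 14)) == 49
        assert age_in_years(b, dt.date(2000, 6, 15)) == 50
        assert last_day_at_age(b, 64) == dt.date(2015, 6, 14)

    def test_config_dates_accept_day_first(self):
        assert parse_date("15/01/1998", allow_dayfirst=True) == dt.date(1998, 1, 15)
        with pytest.raises(ValueError):
            parse_date("15/01/1998")
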