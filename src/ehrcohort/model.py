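"""Domain model for the raw EHR source tables and their flat-file form.

The package consumes a single-source, THIN/CPRD-like relational structure:
a practice table (key dates and last-collection date), a patient table
(demographics and registration lifecycle) and a long coded-event table
covering diagnoses (clinical), prescriptions (therapy) and valued
measurements. Files are plain CSV with a header row; empty string means
missing; dates are ISO-8601.

Rows violating referential integrity or date ordering are dropped at load
time and counted in an :class:`IntegrityReport` so the load is auditable
rather than silently lossy.
"""
from __future__ import annotations

import datetime as dt
import hashlib
from bisect import bisect_left, bisect_right
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .dates import parse_date

TABLES = ("clinical", "therapy", "measurement")

PRACTICE_COLUMNS = ["practice_id", "key_date", "collection_date"]
PATIENT_COLUMNS = [
    "patient_id", "practice_id", "sex", "birth_date", "birth_precision",
    "registration_date", "deregistration_date", "death_date",
    "townsend_quintile", "ethnicity",
]
EVENT_COLUMNS = ["patient_id", "code", "event_date", "value", "unit", "table_of_origin"]

_SEX_ALIASES = {"m": "male", "male": "male", "f": "female", "female": "female"}


@dataclass(frozen=True)
class Practice:
    """A general practice; ``key_date`` is the latest of its data-quality
    key dates (computerisation / acceptable-mortality-rate / healthcare
    system), pre-combined at load."""

    practice_id: str
    key_date: dt.date
    collection_date: dt.date


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    practice_id: str
    sex: str  # "male" | "female"
    birth_date: dt.date
    birth_precision: str = "day"  # "day" | "year"
    registration_date: dt.date = None  # type: ignore[assignment]
    deregistration_date: Optional[dt.date] = None
    death_date: Optional[dt.date] = None
    townsend_quintile: Optional[int] = None
    ethnicity: Optional[str] = None


@dataclass(frozen=True)
class CodedEvent:
    patient_id: str
    code: str
    event_date: dt.date
    value: Optional[float] = None
    unit: Optional[str] = None
    table_of_origin: str = "clinical"

    def sort_key(self):
        return (self.event_date, self.code, self.table_of_origin)


@dataclass
class IntegrityReport:
    """Counts of rows dropped (or practices refused) during load."""

    counts: Counter = field(default_factory=Counter)
    samples: dict = field(default_factory=dict)

    def record(self, issue: str, detail: str = "") -> None:
        self.counts[issue] += 1
        self.samples.setdefault(issue, [])
        if len(self.samples[issue]) < 5:
            self.samples[issue].append(detail)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


class EHRDatabase:
    """In-memory single-source EHR database with per-patient event indexes.

    Events are held per patient, sorted by (date, code, table_of_origin) so
    every "earliest event" rule in the pipeline is deterministic.
    """

    def __init__(
        self,
        practices: Mapping[str, Practice],
        patients: Mapping[str, PatientRecord],
        events: Iterable[CodedEvent],
        integrity: Optional[IntegrityReport] = None,
    ) -> None:
        self.practices: dict[str, Practice] = dict(practices)
        self.patients: dict[str, PatientRecord] = dict(patients)
        self.events_by_patient: dict[str, list[CodedEvent]] = {}
        for ev in events:
            self.events_by_patient.setdefault(ev.patient_id, []).append(ev)
        for evs in self.events_by_patient.values():
            evs.sort(key=CodedEvent.sort_key)
        self._date_index: dict[str, list[dt.date]] = {
            pid: [e.event_date for e in evs]
            for pid, evs in self.events_by_patient.items()
        }
        self.integrity = integrity or IntegrityReport()

    # -- queries ---------------------------------------------------------
    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_events(self) -> int:
        return sum(len(v) for v in self.events_by_patient.values())

    def events_of(self, patient_id: str) -> Sequence[CodedEvent]:
        return self.events_by_patient.get(patient_id, [])

    def events_for(
        self,
        patient_id: str,
        codes: Iterable[str],
        window: tuple[dt.date, dt.date],
    ) -> list[CodedEvent]:
        """All events of a patient with code in ``codes`` and date inside the
        closed ``window``, in (date, code, table) order. Unknown patient ->
        empty list."""
        start, end = window
        if start > end:
            raise ValueError("window start must be <= window end")
        evs = self.events_by_patient.get(patient_id)
        if not evs:
            return []
        dates = self._date_index[patient_id]
        lo = bisect_left(dates, start)
        hi = bisect_right(dates, end)
        codeset = set(codes)
        return [e for e in evs[lo:hi] if e.code in codeset]

    def first_event(
        self,
        patient_id: str,
        codes: Iterable[str],
        not_after: Optional[dt.date] = None,
        not_before: Optional[dt.date] = None,
    ) -> Optional[CodedEvent]:
        """Earliest matching event within the optional closed bounds."""
        evs = self.events_by_patient.get(patient_id)
        if not evs:
            return None
        codeset = set(codes)
        for e in evs:
            if not_after is not None and e.event_date > not_after:
                break
            if not_before is not None and e.event_date < not_before:
                continue
            if e.code in codeset:
                return e
        return None

    def digest(self) -> str:
        """Stable content hash used by the extraction audit log."""
        h = hashlib.sha256()
        for pid in sorted(self.practices):
            p = self.practices[pid]
            h.update(f"P|{pid}|{p.key_date}|{p.collection_date}\n".encode())
        for pid in sorted(self.patients):
            r = self.patients[pid]
            h.update(
                f"p|{pid}|{r.practice_id}|{r.sex}|{r.birth_date}|{r.birth_precision}|"
                f"{r.registration_date}|{r.deregistration_date}|{r.death_date}|"
                f"{r.townsend_quintile}|{r.ethnicity}\n".encode()
            )
        for pid in sorted(self.events_by_patient):
            for e in self.events_by_patient[pid]:
                h.update(
                    f"e|{pid}|{e.code}|{e.event_date}|{e.value}|{e.unit}|"
                    f"{e.table_of_origin}\n".encode()
                )
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Flat-file I/O
# ---------------------------------------------------------------------------

def _opt_date(cell: str, report: IntegrityReport, issue: str) -> tuple[Optional[dt.date], bool]:
    if cell == "":
        return None, True
    try:
        return parse_date(cell), True
    except ValueError:
        report.record(issue, cell)
        return None, False


def load_database(
    database_dir: str | Path | None = None,
    *,
    practice_path: str | Path | None = None,
    patient_path: str | Path | None = None,
    events_path: str | Path | None = None,
    year_birth_anchor: tuple[int, int] = (7, 1),
) -> EHRDatabase:
    """Load and validate the three CSV tables into an :class:`EHRDatabase`.

    ``year_birth_anchor`` is the (month, day) assigned to year-precision
    birth dates for age arithmetic; July 1 by default, January 1 available.

    Missing file -> :class:`FileNotFoundError`. Duplicate practice_id ->
    :class:`ValueError` (fatal). Row-level problems (unparseable dates,
    dangling foreign keys, inverted date order) drop the row and are counted
    in ``db.integrity``.
    """
    if database_dir is not None:
        d = Path(database_dir)
        practice_path = practice_path or d / "practice.csv"
        patient_path = patient_path or d / "patient.csv"
        events_path = events_path or d / "events.csv"
    for p in (practice_path, patient_path, events_path):
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required table file missing: {p}")

    report = IntegrityReport()
    prac_df = pd.read_csv(practice_path, dtype=str, keep_default_na=False)
    pat_df = pd.read_csv(patient_path, dtype=str, keep_default_na=False)
    ev_df = pd.read_csv(events_path, dtype=str, keep_default_na=False)
    for df, cols, name in (
        (prac_df, PRACTICE_COLUMNS, "practice"),
        (pat_df, PATIENT_COLUMNS, "patient"),
        (ev_df, EVENT_COLUMNS, "events"),
    ):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name}.csv is missing columns: {missing}")

    practices: dict[str, Practice] = {}
    for row in prac_df.itertuples(index=False):
        pid = row.practice_id
        if pid in practices:
            raise ValueError(f"duplicate practice_id: {pid}")
        key_date, ok1 = _opt_date(row.key_date, report, "practice_bad_date")
        coll, ok2 = _opt_date(row.collection_date, report, "practice_bad_date")
        if not (ok1 and ok2) or key_date is None or coll is None:
            report.record("practice_row_dropped", pid)
            continue
        if key_date > coll:
            report.record("practice_key_after_collection", pid)
            continue
        practices[pid] = Practice(pid, key_date, coll)

    patients: dict[str, PatientRecord] = {}
    anchor_m, anchor_d = year_birth_anchor
    for row in pat_df.itertuples(index=False):
        pid = row.patient_id
        if pid in patients:
            report.record("patient_duplicate_id", pid)
            continue
        if row.practice_id not in practices:
            report.record("patient_unknown_practice", pid)
            continue
        sex = _SEX_ALIASES.get(row.sex.strip().lower())
        if sex is None:
            report.record("patient_bad_sex", pid)
            continue
        precision = (row.birth_precision or "day").strip().lower()
        if precision not in ("day", "year"):
            report.record("patient_bad_birth_precision", pid)
            continue
        birth, ok = _opt_date(row.birth_date, report, "patient_bad_date")
        reg, ok2 = _opt_date(row.registration_date, report, "patient_bad_date")
        dereg, ok3 = _opt_date(row.deregistration_date, report, "patient_bad_date")
        death, ok4 = _opt_date(row.death_date, report, "patient_bad_date")
        if not (ok and ok2 and ok3 and ok4) or birth is None or reg is None:
            report.record("patient_row_dropped", pid)
            continue
        if precision == "year":
            birth = dt.date(birth.year, anchor_m, anchor_d)
        if (dereg is not None and dereg < reg) or (death is not None and death < reg):
            report.record("patient_exit_before_registration", pid)
            continue
        townsend: Optional[int] = None
        if row.townsend_quintile != "":
            try:
                townsend = int(row.townsend_quintile)
            except ValueError:
                report.record("patient_bad_townsend", pid)
                continue
            if not 1 <= townsend <= 5:
                report.record("patient_bad_townsend", pid)
                continue
        patients[pid] = PatientRecord(
            patient_id=pid,
            practice_id=row.practice_id,
            sex=sex,
            birth_date=birth,
            birth_precision=precision,
            registration_date=reg,
            deregistration_date=dereg,
            death_date=death,
            townsend_quintile=townsend,
            ethnicity=row.ethnicity or None,
        )

    events: list[CodedEvent] = []
    for row in ev_df.itertuples(index=False):
        if row.patient_id not in patients:
            report.record("event_unknown_patient", row.patient_id)
            continue
        date, ok = _opt_date(row.event_date, report, "event_bad_date")
        if not ok or date is None:
            report.record("event_row_dropped", row.patient_id)
            continue
        if row.table_of_origin not in TABLES:
            report.record("event_bad_table", row.table_of_origin)
            continue
        value: Optional[float] = None
        if row.value != "":
            try:
                value = float(row.value)
            except ValueError:
                report.record("event_bad_value", row.patient_id)
                continue
        events.append(
            CodedEvent(row.patient_id, row.code, date, value, row.unit or None,
                       row.table_of_origin)
        )
    return EHRDatabase(practices, patients, events, report)


def write_database(db: EHRDatabase, out_dir: str | Path) -> None:
    """Write the database back to the three-CSV flat-file form (round-trips
    with :func:`load_database`)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prac_rows = [
        {"practice_id": p.practice_id, "key_date": p.key_date.isoformat(),
         "collection_date": p.collection_date.isoformat()}
        for p in sorted(db.practices.values(), key=lambda p: p.practice_id)
    ]
    pd.DataFrame(prac_rows, columns=PRACTICE_COLUMNS).to_csv(out / "practice.csv", index=False)

    def _s(d: Optional[dt.date]) -> str:
        return "" if d is None else d.isoformat()

    pat_rows = [
        {
            "patient_id": r.patient_id, "practice_id": r.practice_id, "sex": r.sex,
            "birth_date": r.birth_date.isoformat(), "birth_precision": r.birth_precision,
            "registration_date": r.registration_date.isoformat(),
            "deregistration_date": _s(r.deregistration_date),
            "death_date": _s(r.death_date),
            "townsend_quintile": "" if r.townsend_quintile is None else r.townsend_quintile,
            "ethnicity": r.ethnicity or "",
        }
        for r in sorted(db.patients.values(), key=lambda r: r.patient_id)
    ]
    pd.DataFrame(pat_rows, columns=PATIENT_COLUMNS).to_csv(out / "patient.csv", index=False)

    ev_rows = [
        {
            "patient_id": e.patient_id, "code": e.code,
            "event_date": e.event_date.isoformat(),
            "value": "" if e.value is None else repr(e.value) if e.value != int(e.value) else str(e.value),
            "unit": e.unit or "", "table_of_origin": e.table_of_origin,
        }
        for pid in sorted(db.events_by_patient)
        for e in db.events_by_patient[pid]
    ]
    pd.DataFrame(ev_rows, columns=EVENT_COLUMNS).to_csv(out / "events.csv", index=False)
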