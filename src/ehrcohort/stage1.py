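"""Stage 1 — the study-eligible period.

Each practice contributes an eligible interval clipped by its data-quality
key date (plus an optional offset) and last collection date; each patient's
observation window is then the intersection of registration lifecycle,
practice interval and the age limits. Patients failing the sex filter, the
entry-age ceiling, or ending with an empty window are rejected with a
documented reason; everyone else becomes a candidate cohort member.

Rejection reasons follow the order the checks are listed in the stage-1
transformation logic (age ceiling, then sex, then window overlap), so
attrition tables are reproducible.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

from .audit import RejectionLog
from .dates import age_in_years, attain_age_date, fmt, last_day_at_age, parse_date
from .design import StudyDesign, StudyPeriodSpec
from .model import EHRDatabase, PatientRecord, Practice

# Fixed rejection-reason vocabulary for this stage.
R_PRACTICE_EMPTY = "practice window empty"
R_AGE_MAX = "age at entry above maximum"
R_SEX = "sex excluded"
R_NO_OVERLAP = "no overlap with practice window"
R_EMPTY_WINDOW = "patient window empty"

ROLE_CANDIDATE = "candidate"
ROLE_EXPOSED = "exposed_or_case"
ROLE_POTENTIAL_CONTROL = "potential_control"
ROLE_MATCHED_CONTROL = "matched_control"
ROLE_UNEXPOSED = "unexposed"  # retained population rows in cross-sectional designs


@dataclass(frozen=True)
class ObservationWindow:
    patient_start: dt.date
    patient_end: dt.date
    practice_start: dt.date
    practice_end: dt.date


@dataclass
class CohortMember:
    """A patient carried through the pipeline stages."""

    patient_id: str
    practice_id: str
    window: ObservationWindow
    role: str = ROLE_CANDIDATE
    index_date: Optional[dt.date] = None
    group_id: Optional[int] = None
    match_order: Optional[int] = None
    exit_date: Optional[dt.date] = None
    entity_dates: dict[str, dt.date] = field(default_factory=dict)
    control_entity_date: Optional[dt.date] = None
    outcome_dates: dict[str, Optional[dt.date]] = field(default_factory=dict)
    baselines: dict[str, tuple[Optional[float], Optional[dt.date]]] = field(default_factory=dict)

    # -- checkpoint (de)serialization -----------------------------------
    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "practice_id": self.practice_id,
            "window": [fmt(self.window.patient_start), fmt(self.window.patient_end),
                       fmt(self.window.practice_start), fmt(self.window.practice_end)],
            "role": self.role,
            "index_date": fmt(self.index_date),
            "group_id": self.group_id,
            "match_order": self.match_order,
            "exit_date": fmt(self.exit_date),
            "entity_dates": {k: fmt(v) for k, v in self.entity_dates.items()},
            "control_entity_date": fmt(self.control_entity_date),
            "outcome_dates": {k: fmt(v) for k, v in self.outcome_dates.items()},
            "baselines": {k: [v[0], fmt(v[1])] for k, v in self.baselines.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortMember":
        def _d(s):
            return parse_date(s) if s else None

        w = d["window"]
        return cls(
            patient_id=d["patient_id"],
            practice_id=d["practice_id"],
            window=ObservationWindow(_d(w[0]), _d(w[1]), _d(w[2]), _d(w[3])),
            role=d["role"],
            index_date=_d(d["index_date"]),
            group_id=d["group_id"],
            match_order=d["match_order"],
            exit_date=_d(d["exit_date"]),
            entity_dates={k: _d(v) for k, v in d["entity_dates"].items()},
            control_entity_date=_d(d["control_entity_date"]),
            outcome_dates={k: _d(v) for k, v in d["outcome_dates"].items()},
            baselines={k: (v[0], _d(v[1])) for k, v in d["baselines"].items()},
        )


def practice_window(practice: Practice, spec: StudyPeriodSpec) -> Optional[tuple[dt.date, dt.date]]:
    """Eligible interval of a practice, or ``None`` when empty.

    start = max(key_date + offset, study_start); end = min(study_end,
    collection_date).
    """
    start = max(practice.key_date + dt.timedelta(days=spec.key_date_offset_days),
                spec.study_start)
    end = min(spec.study_end, practice.collection_date)
    if start > end:
        return None
    return start, end


def patient_window(
    patient: PatientRecord,
    practice_interval: tuple[dt.date, dt.date],
    spec: StudyPeriodSpec,
) -> tuple[Optional[ObservationWindow], Optional[str]]:
    """Observation window for one patient, or (None, rejection reason)."""
    practice_start, practice_end = practice_interval
    start = max(
        patient.registration_date + dt.timedelta(days=spec.registration_leadin_days),
        practice_start,
        attain_age_date(patient.birth_date, spec.entry_age_min),
    )
    end_candidates = [practice_end, last_day_at_age(patient.birth_date, spec.exit_age_max)]
    if patient.deregistration_date is not None:
        end_candidates.append(patient.deregistration_date)
    if patient.death_date is not None:
        end_candidates.append(patient.death_date)
    end = min(end_candidates)

    if age_in_years(patient.birth_date, start) > spec.entry_age_max:
        return None, R_AGE_MAX
    if spec.sex_filter != "any" and patient.sex != spec.sex_filter:
        return None, R_SEX
    # Literal reading of the stage-1 text: strict before/after for the
    # practice-overlap test, even though all other intervals are closed.
    if not (start < practice_end and end > practice_start):
        return None, R_NO_OVERLAP
    if start > end:
        return None, R_EMPTY_WINDOW
    return ObservationWindow(start, end, practice_start, practice_end), None


def run_stage1(db: EHRDatabase, design: StudyDesign, log: RejectionLog) -> list[CohortMember]:
    """Filter the whole database population to candidate cohort members.

    Patients of practices with an empty eligible interval are rejected as
    "practice window empty". The output is sorted by patient id, so it is
    independent of input ordering.
    """
    members: list[CohortMember] = []
    spec = design.period
    intervals = {pid: practice_window(p, spec) for pid, p in db.practices.items()}
    for patient in db.patients.values():
        interval = intervals.get(patient.practice_id)
        if interval is None:
            log.record("stage1", R_PRACTICE_EMPTY, patient.patient_id)
            continue
        window, reason = patient_window(patient, interval, spec)
        if window is None:
            log.record("stage1", reason, patient.patient_id)
            continue
        members.append(CohortMember(patient.patient_id, patient.practice_id, window))
    members.sort(key=lambda m: m.patient_id)
    return members
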