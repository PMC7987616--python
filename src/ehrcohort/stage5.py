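"""Stage 5 — first post-index outcomes and the patient exit date.

Outcomes are sought strictly after the index date (same-day events belong
to the pre-index exclusion logic, so a same-day outcome can never create
zero-length immortal follow-up) and no later than the patient end date.
The exit date is the patient end date unless any outcome occurred first;
each outcome's own first date is also recorded so analysts can apply
cause-specific censoring.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

from .design import CodeEntity, StudyDesign
from .model import EHRDatabase
from .stage1 import CohortMember


@dataclass(frozen=True)
class OutcomeRecord:
    patient_id: str
    outcome_name: str
    event_date: Optional[dt.date]  # None = censored


def run_stage5(
    members: Sequence[CohortMember],
    outcomes: Sequence[CodeEntity],
    db: EHRDatabase,
) -> list[OutcomeRecord]:
    """Assign ``exit_date`` to every member and record per-outcome firsts.

    Every member must already carry an index date (matched controls carry
    their group's). Follow-up ``exit_date - index_date`` is always >= 0.
    """
    records: list[OutcomeRecord] = []
    for member in members:
        if member.index_date is None:
            raise ValueError(f"member {member.patient_id} has no index date at stage 5")
        end = member.window.patient_end
        exit_date = end
        for entity in outcomes:
            ev = db.first_event(
                member.patient_id, entity.definition,
                not_before=member.index_date + dt.timedelta(days=1),
                not_after=end,
            )
            date = ev.event_date if ev is not None else None
            member.outcome_dates[entity.name] = date
            records.append(OutcomeRecord(member.patient_id, entity.name, date))
            if date is not None and date < exit_date:
                exit_date = date
        member.exit_date = exit_date
    return records


def outcome_entities(design: StudyDesign) -> list[CodeEntity]:
    return [design.entity(name) for name in design.outcomes]
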