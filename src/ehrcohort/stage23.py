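"""Stages 2 and 3 — index-date assignment and the control pool.

Stage 2 locates every inclusion code entity referenced by the exposure
logic inside each candidate's observation window, evaluates the combination
logic in the design's parsing mode, and either assigns an index date
(role exposed_or_case), diverts the patient to the potential-control pool
(when controls are required), retains them as an unexposed population row
(cross-sectional designs), or rejects them with a documented reason.
Exclusion entities and the optional pre-index outcome restriction are then
applied to the exposed.

Stage 3 refines the potential-control pool with the same machinery driven
by the control logic; because controls have no index date yet, only
"exclude if ever recorded" exclusions apply here — index-relative control
exclusions belong to the matching stage.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional

from .audit import RejectionLog
from .design import CodeEntity, CombinationLogic, StudyDesign
from .logic import StrictResult, evaluate_loose, evaluate_strict
from .model import CodedEvent, EHRDatabase
from .stage1 import (CohortMember, ROLE_EXPOSED, ROLE_POTENTIAL_CONTROL,
                     ROLE_UNEXPOSED)

R_PREVALENT = "prevalent at entry: {name}"
R_LOGIC_UNSAT = "exposure logic unsatisfied"
R_LOGIC_ORDER = "exposure order violated"
R_EXCL_EVER = "exclusion ({name}) ever recorded"
R_EXCL_BEFORE = "exclusion ({name}) before index"
R_OUTCOME_BEFORE = "outcome ({name}) before index"
R_CTRL_PREVALENT = "control prevalent at entry: {name}"
R_CTRL_UNSAT = "control logic unsatisfied"
R_CTRL_ORDER = "control logic order violated"
R_CTRL_EXCL_EVER = "control exclusion ({name}) ever recorded"


@dataclass(frozen=True)
class EntityHit:
    entity_name: str
    event_date: dt.date
    source_event: CodedEvent


def locate_entity(
    member: CohortMember, entity: CodeEntity, db: EHRDatabase
) -> tuple[str, Optional[EntityHit], Optional[str]]:
    """Locate the qualifying event of one inclusion entity.

    Returns ``("hit", EntityHit, None)``, ``("none", None, None)`` or
    ``("reject", None, reason)``. The incident-only rule rejects patients
    whose earliest record precedes cohort entry (prevalent at entry).
    """
    w = member.window
    etype = entity.exposure_type
    if etype == "first_after_entry":
        ev = db.first_event(member.patient_id, entity.definition,
                            not_before=w.patient_start, not_after=w.patient_end)
        if ev is None:
            return "none", None, None
        return "hit", EntityHit(entity.name, ev.event_date, ev), None
    ev = db.first_event(member.patient_id, entity.definition, not_after=w.patient_end)
    if ev is None:
        return "none", None, None
    if etype == "incident_only" and ev.event_date < w.patient_start:
        return "reject", None, R_PREVALENT.format(name=entity.name)
    return "hit", EntityHit(entity.name, ev.event_date, ev), None


def _entity_dates(
    member: CohortMember,
    logic: CombinationLogic,
    design: StudyDesign,
    db: EHRDatabase,
) -> tuple[Optional[dict[str, Optional[dt.date]]], Optional[str]]:
    """Dates contributed by every entity the logic references, or a
    rejection reason. Prevalent incident-or-prevalent hits contribute the
    cohort-entry date (the patient is at risk from entry)."""
    dates: dict[str, Optional[dt.date]] = {}
    for entity in design.logic_entities(logic):
        status, hit, reason = locate_entity(member, entity, db)
        if status == "reject":
            return None, reason
        if status == "none":
            dates[entity.name] = None
        else:
            d = hit.event_date
            if entity.exposure_type == "incident_or_prevalent" and d < member.window.patient_start:
                d = member.window.patient_start
            dates[entity.name] = d
    return dates, None


def assign_index(
    member: CohortMember, design: StudyDesign, db: EHRDatabase, log: RejectionLog
) -> str:
    """Evaluate the exposure logic for one stage-1 member.

    Returns the resulting status: ``"exposed"``, ``"potential_control"``,
    ``"unexposed"`` (cross-sectional retention) or ``"rejected"``.
    """
    dates, reason = _entity_dates(member, design.exposure_logic, design, db)
    if dates is None:
        log.record("stage2", reason, member.patient_id)
        return "rejected"
    ast = design.exposure_logic.ast

    if design.exposure_logic.mode == "strict":
        res = evaluate_strict(ast, dates)
        if res.status == StrictResult.DATE:
            index: Optional[dt.date] = res.date
        elif res.status == StrictResult.REJECT_ORDER:
            log.record("stage2", R_LOGIC_ORDER, member.patient_id)
            return "rejected"
        else:
            index = None
    else:
        index = evaluate_loose(ast, dates)

    if index is not None:
        member.role = ROLE_EXPOSED
        member.index_date = index
        member.entity_dates = {k: v for k, v in dates.items() if v is not None}
        return "exposed"
    if design.controls_required:
        member.role = ROLE_POTENTIAL_CONTROL
        return "potential_control"
    if design.design_type == "cross_sectional":
        member.role = ROLE_UNEXPOSED
        return "unexposed"
    log.record("stage2", R_LOGIC_UNSAT, member.patient_id)
    return "rejected"


def apply_exclusions(
    member: CohortMember, design: StudyDesign, db: EHRDatabase, log: RejectionLog
) -> bool:
    """Stage-2 exclusion entities and pre-index outcome restriction for an
    exposed/case member; returns True when the member is kept."""
    pid = member.patient_id
    for entity in design.exclusion_entities():
        if entity.exposure_type == "exclude_ever":
            if db.first_event(pid, entity.definition) is not None:
                log.record("stage2", R_EXCL_EVER.format(name=entity.name), pid)
                return False
        else:  # exclude_before_index — inclusive of the index day
            if db.first_event(pid, entity.definition, not_after=member.index_date) is not None:
                log.record("stage2", R_EXCL_BEFORE.format(name=entity.name), pid)
                return False
    if design.pre_index_outcome_exclusion:
        for name in design.outcomes:
            entity = design.entity(name)
            if db.first_event(pid, entity.definition, not_after=member.index_date) is not None:
                log.record("stage2", R_OUTCOME_BEFORE.format(name=name), pid)
                return False
    return True


def run_stage2(
    members: list[CohortMember], design: StudyDesign, db: EHRDatabase, log: RejectionLog
) -> tuple[list[CohortMember], list[CohortMember], list[CohortMember]]:
    """Partition stage-1 candidates into (exposed, potential controls,
    retained unexposed). Every other member is rejected with a reason."""
    exposed: list[CohortMember] = []
    pool: list[CohortMember] = []
    retained: list[CohortMember] = []
    for member in members:
        status = assign_index(member, design, db, log)
        if status == "exposed":
            if apply_exclusions(member, design, db, log):
                exposed.append(member)
        elif status == "potential_control":
            pool.append(member)
        elif status == "unexposed":
            retained.append(member)
    return exposed, pool, retained


def run_stage3(
    pool: list[CohortMember], design: StudyDesign, db: EHRDatabase, log: RejectionLog
) -> list[CohortMember]:
    """Refine the potential-control pool with the control logic.

    With no control logic declared the pool passes through unchanged (the
    unexposed group is simply "absence of the exposure").
    """
    logic = design.control_logic
    if logic is None:
        return pool
    survivors: list[CohortMember] = []
    for member in pool:
        dates, reason = _entity_dates(member, logic, design, db)
        if dates is None:
            log.record("stage3", "control " + reason, member.patient_id)
            continue
        if logic.mode == "strict":
            res = evaluate_strict(logic.ast, dates)
            if res.status == StrictResult.REJECT_ORDER:
                log.record("stage3", R_CTRL_ORDER, member.patient_id)
                continue
            date = res.date if res.status == StrictResult.DATE else None
        else:
            date = evaluate_loose(logic.ast, dates)
        if date is None:
            log.record("stage3", R_CTRL_UNSAT, member.patient_id)
            continue
        excluded = False
        for entity in design.exclusion_entities():
            if entity.exposure_type != "exclude_ever":
                continue  # index-relative exclusions are applied at matching
            if db.first_event(member.patient_id, entity.definition) is not None:
                log.record("stage3", R_CTRL_EXCL_EVER.format(name=entity.name),
                           member.patient_id)
                excluded = True
                break
        if excluded:
            continue
        member.control_entity_date = date
        survivors.append(member)
    return survivors
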