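"""Workflow control: the staged extraction plan, checkpoints and resume.

The plan is a pure function of the design: cohort and case-control studies
run all six stages (control selection and matching only when controls are
required); cross-sectional studies skip control selection, matching and
outcome determination. After every stage the full pipeline state is written
to a JSON checkpoint keyed by digests of the design and the database, so an
interrupted run resumes from the last completed stage and produces outputs
identical to an uninterrupted run. Stage 4 is the only consumer of
randomness; its generator is constructed from the study seed at the moment
the stage starts, which is what makes resumption exact.
"""
from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .audit import AuditConsistencyError, ExtractionLog, RejectionLog, attrition_table
from .crypto import encrypt_output
from .design import StudyDesign
from .model import EHRDatabase, load_database
from .stage1 import CohortMember, run_stage1
from .stage23 import run_stage2, run_stage3
from .stage4 import MatchedSet, run_stage4
from .stage5 import outcome_entities, run_stage5
from .stage6 import assemble, write_dataset

STAGE_NAMES = ("stage1", "stage2", "stage3", "stage4", "stage5", "stage6")


@dataclass(frozen=True)
class StagePlan:
    stages: tuple[tuple[str, bool], ...]

    def enabled(self) -> tuple[str, ...]:
        return tuple(name for name, on in self.stages if on)

    def is_enabled(self, name: str) -> bool:
        return name in self.enabled()


def plan(design: StudyDesign) -> StagePlan:
    """Deterministic stage plan for a validated design."""
    cross = design.design_type == "cross_sectional"
    controls = design.controls_required
    return StagePlan((
        ("stage1", True),
        ("stage2", True),
        ("stage3", not cross and controls),
        ("stage4", not cross and controls),
        ("stage5", not cross),
        ("stage6", True),
    ))


@dataclass
class PipelineState:
    """Everything the stages pass forward; serializable for checkpoints."""

    members: list[CohortMember] = field(default_factory=list)
    exposed: list[CohortMember] = field(default_factory=list)
    pool: list[CohortMember] = field(default_factory=list)
    retained: list[CohortMember] = field(default_factory=list)
    matched_controls: list[CohortMember] = field(default_factory=list)
    matched_sets: list[MatchedSet] = field(default_factory=list)
    log: RejectionLog = field(default_factory=RejectionLog)
    stage_io: dict[str, tuple[int, int]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def final_members(self, design: StudyDesign) -> list[CohortMember]:
        if design.design_type == "cross_sectional":
            return self.exposed + self.retained
        return self.exposed + self.matched_controls

    # -- checkpoint serialization ---------------------------------------
    def as_dict(self) -> dict:
        def ids(ms):
            return [m.patient_id for m in ms]

        all_members = {m.patient_id: m for m in
                       self.members + self.exposed + self.pool + self.retained
                       + self.matched_controls}
        return {
            "members": [m.as_dict() for m in sorted(all_members.values(),
                                                    key=lambda m: m.patient_id)],
            "lists": {
                "members": ids(self.members), "exposed": ids(self.exposed),
                "pool": ids(self.pool), "retained": ids(self.retained),
                "matched_controls": ids(self.matched_controls),
            },
            "matched_sets": [
                {"group_id": s.group_id, "exposed_id": s.exposed_id,
                 "control_ids": list(s.control_ids),
                 "index_date": s.index_date.isoformat()}
                for s in self.matched_sets
            ],
            "log": self.log.as_dict(),
            "stage_io": {k: list(v) for k, v in self.stage_io.items()},
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineState":
        by_id = {d["patient_id"]: CohortMember.from_dict(d) for d in data["members"]}
        lists = data["lists"]
        state = cls(
            members=[by_id[i] for i in lists["members"]],
            exposed=[by_id[i] for i in lists["exposed"]],
            pool=[by_id[i] for i in lists["pool"]],
            retained=[by_id[i] for i in lists["retained"]],
            matched_controls=[by_id[i] for i in lists["matched_controls"]],
            matched_sets=[
                MatchedSet(s["group_id"], s["exposed_id"], tuple(s["control_ids"]),
                           dt.date.fromisoformat(s["index_date"]))
                for s in data["matched_sets"]
            ],
            log=RejectionLog.from_dict(data["log"]),
            stage_io={k: (v[0], v[1]) for k, v in data["stage_io"].items()},
            notes=list(data["notes"]),
        )
        return state


def _run_stage(name: str, state: PipelineState, db: EHRDatabase,
               design: StudyDesign, seed: int) -> None:
    if name == "stage1":
        n_in = db.n_patients
        state.members = run_stage1(db, design, state.log)
        state.stage_io["stage1"] = (n_in, len(state.members))
    elif name == "stage2":
        n_in = len(state.members)
        state.exposed, state.pool, state.retained = run_stage2(
            state.members, design, db, state.log)
        state.stage_io["stage2"] = (
            n_in, len(state.exposed) + len(state.pool) + len(state.retained))
    elif name == "stage3":
        n_in = len(state.pool)
        state.pool = run_stage3(state.pool, design, db, state.log)
        state.stage_io["stage3"] = (n_in, len(state.pool))
    elif name == "stage4":
        n_in = len(state.exposed) + len(state.pool)
        rng = np.random.default_rng(seed)
        sets, kept, controls = run_stage4(
            state.exposed, state.pool, design.match_criteria, db, rng,
            state.log, design=design, notes=state.notes)
        state.matched_sets, state.exposed, state.matched_controls = sets, kept, controls
        state.pool = []
        state.stage_io["stage4"] = (n_in, len(kept) + len(controls))
    elif name == "stage5":
        members = state.final_members(design)
        run_stage5(members, outcome_entities(design), db)
        state.stage_io["stage5"] = (len(members), len(members))
    elif name == "stage6":
        members = state.final_members(design)
        state.stage_io["stage6"] = (len(members), len(members))
    else:  # pragma: no cover
        raise ValueError(f"unknown stage {name}")


@dataclass
class RunResult:
    dataset: pd.DataFrame
    attrition: pd.DataFrame
    state: PipelineState
    extraction_log: ExtractionLog
    verdict: bool


def extract(
    db: EHRDatabase,
    design: StudyDesign,
    seed: Optional[int] = None,
    capture_ids: bool = False,
) -> RunResult:
    """Run the full staged extraction in memory and verify attrition.

    The in-memory twin of :func:`run`; no checkpoints or files. ``seed``
    overrides the design's seed for the matching stage.
    """
    use_seed = design.seed if seed is None else seed
    state = PipelineState(log=RejectionLog(capture_ids=capture_ids))
    stage_plan = plan(design)
    for name in stage_plan.enabled():
        _run_stage(name, state, db, design, use_seed)
    dataset = assemble(state.final_members(design), design, db, state.matched_sets)
    xlog = ExtractionLog(design.digest(), db.digest(), use_seed, __version__)
    xlog.stage_io_counts = {k: list(v) for k, v in state.stage_io.items()}
    xlog.notes = state.notes
    try:
        attrition = attrition_table(state.log, state.stage_io)
        verdict = len(dataset) + state.log.total() == db.n_patients
        if not verdict:
            xlog.note("global conservation violated")
    except AuditConsistencyError as exc:
        attrition = attrition_table(state.log, state.stage_io, verify=False)
        xlog.note(str(exc))
        verdict = False
    xlog.status = "completed" if verdict else "failed"
    return RunResult(dataset, attrition, state, xlog, verdict)


def run(
    db_path: str | Path | EHRDatabase,
    design_path: str | Path | StudyDesign,
    out_dir: str | Path,
    seed_override: Optional[int] = None,
    resume: bool = False,
    stop_after: Optional[str] = None,
    encrypt_password: Optional[str] = None,
    capture_ids: bool = False,
) -> RunResult:
    """Checkpointed extraction run writing the output files.

    Outputs in ``out_dir``: ``dataset.csv`` (or ``dataset.csv.enc`` when a
    password is supplied), ``attrition.csv``, ``extraction_log.json`` and a
    ``checkpoints/`` directory. With ``resume`` the run continues from the
    last checkpoint whose design/database digests match. ``stop_after``
    stops the run after the named stage (used to exercise interruption).
    """
    db = db_path if isinstance(db_path, EHRDatabase) else load_database(db_path)
    design = (design_path if isinstance(design_path, StudyDesign)
              else StudyDesign.from_file(design_path))
    out = Path(out_dir)
    ckpt_dir = out / "checkpoints"
    ckpt_dir.mkdir(parents=True, exist_ok=True)
    use_seed = design.seed if seed_override is None else seed_override
    password = encrypt_password if encrypt_password is not None else design.encrypt_password

    design_digest, db_digest = design.digest(), db.digest()
    xlog = ExtractionLog(design_digest, db_digest, use_seed, __version__)
    stage_plan = plan(design)
    enabled = stage_plan.enabled()

    state = PipelineState(log=RejectionLog(capture_ids=capture_ids))
    start_at = 0
    if resume:
        for i in range(len(enabled) - 1, -1, -1):
            path = ckpt_dir / f"{enabled[i]}.json"
            if not path.exists():
                continue
            data = json.loads(path.read_text())
            if (data.get("design_digest") == design_digest
                    and data.get("database_digest") == db_digest
                    and data.get("seed") == use_seed):
                state = PipelineState.from_dict(data["state"])
                start_at = i + 1
                break

    try:
        for name in enabled[start_at:]:
            _run_stage(name, state, db, design, use_seed)
            payload = {
                "stage": name,
                "design_digest": design_digest,
                "database_digest": db_digest,
                "seed": use_seed,
                "state": state.as_dict(),
            }
            (ckpt_dir / f"{name}.json").write_text(json.dumps(payload))
            if stop_after == name:
                xlog.status = "interrupted"
                xlog.stage_io_counts = {k: list(v) for k, v in state.stage_io.items()}
                xlog.write(out / "extraction_log.json")
                return RunResult(pd.DataFrame(), pd.DataFrame(), state, xlog, False)

        dataset = assemble(state.final_members(design), design, db, state.matched_sets)
        xlog.stage_io_counts = {k: list(v) for k, v in state.stage_io.items()}
        xlog.notes = state.notes
        attrition = attrition_table(state.log, state.stage_io)
        verdict = len(dataset) + state.log.total() == db.n_patients
        if not verdict:
            xlog.note("global conservation violated")
        xlog.status = "completed" if verdict else "failed"

        plain = write_dataset(dataset, None)
        if password:
            (out / "dataset.csv.enc").write_bytes(encrypt_output(plain, password))
        else:
            (out / "dataset.csv").write_bytes(plain)
        attrition.to_csv(out / "attrition.csv", index=False)
        xlog.write(out / "extraction_log.json")
        return RunResult(dataset, attrition, state, xlog, verdict)
    except AuditConsistencyError as exc:
        xlog.status = "failed"
        xlog.note(str(exc))
        xlog.stage_io_counts = {k: list(v) for k, v in state.stage_io.items()}
        xlog.write(out / "extraction_log.json")
        raise
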