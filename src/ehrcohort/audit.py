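"""Rejection accounting and the per-extraction audit log.

Every patient removed at any stage is counted under a documented reason
string in a per-stage map (reason -> count). The attrition table derived
from those maps, together with per-stage input/output counts, carries the
pipeline's verifiability guarantee: at every stage
``in_count - out_count == sum of that stage's rejection counts``, and a
violation is a hard error, never a warning.
"""
from __future__ import annotations

import datetime as dt
import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

STAGES = ("stage1", "stage2", "stage3", "stage4", "stage5", "stage6")


class AuditConsistencyError(RuntimeError):
    """Raised when rejection counts do not reconcile with stage I/O counts."""


@dataclass
class RejectionLog:
    """Per-stage map from rejection reason to number of patients discarded.

    With ``capture_ids`` on, up to ``sample_cap`` patient ids are retained
    per reason for manual verification of the rejection.
    """

    capture_ids: bool = False
    sample_cap: int = 20
    stages: dict[str, Counter] = field(default_factory=dict)
    samples: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def record(self, stage: str, reason: str, patient_id: Optional[str] = None) -> None:
        counter = self.stages.setdefault(stage, Counter())
        counter[reason] += 1
        if self.capture_ids and patient_id is not None:
            bucket = self.samples.setdefault(stage, {}).setdefault(reason, [])
            if len(bucket) < self.sample_cap:
                bucket.append(patient_id)

    def total(self, stage: Optional[str] = None) -> int:
        if stage is not None:
            return sum(self.stages.get(stage, Counter()).values())
        return sum(sum(c.values()) for c in self.stages.values())

    def as_dict(self) -> dict:
        return {stage: dict(sorted(c.items())) for stage, c in sorted(self.stages.items())}

    @classmethod
    def from_dict(cls, data: Mapping, capture_ids: bool = False) -> "RejectionLog":
        log = cls(capture_ids=capture_ids)
        for stage, reasons in data.items():
            log.stages[stage] = Counter(reasons)
        return log


def record_rejection(log: RejectionLog, stage: str, reason: str,
                     patient_id: Optional[str] = None) -> RejectionLog:
    """Increment the count for ``reason`` (inserting it at 1 if new)."""
    log.record(stage, reason, patient_id)
    return log


def attrition_table(
    log: RejectionLog,
    stage_io_counts: Mapping[str, tuple[int, int]],
    verify: bool = True,
) -> pd.DataFrame:
    """Build the (stage, reason, count) attrition table.

    With ``verify`` (the default) the conservation identity is checked for
    every stage present in ``stage_io_counts`` and an
    :class:`AuditConsistencyError` is raised on any mismatch.
    """
    rows = []
    for stage in sorted(set(log.stages) | set(stage_io_counts)):
        for reason, count in sorted(log.stages.get(stage, Counter()).items()):
            rows.append({"stage": stage, "reason": reason, "count": count})
    table = pd.DataFrame(rows, columns=["stage", "reason", "count"])
    if verify:
        problems = []
        for stage, (n_in, n_out) in stage_io_counts.items():
            rejected = log.total(stage)
            if n_in - n_out != rejected:
                problems.append(
                    f"{stage}: in={n_in} out={n_out} but logged rejections={rejected}")
        if problems:
            raise AuditConsistencyError("; ".join(problems))
    return table


@dataclass
class ExtractionLog:
    """One audit record per extraction attempt, successful or not."""

    design_digest: str
    database_digest: str
    seed: int
    software_version: str
    started_at: str = field(default_factory=lambda: dt.datetime.now(dt.timezone.utc).isoformat())
    stage_io_counts: dict[str, list[int]] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    status: str = "started"  # started | completed | failed

    def note(self, message: str) -> None:
        self.notes.append(message)

    def as_dict(self) -> dict:
        return {
            "started_at": self.started_at,
            "design_digest": self.design_digest,
            "database_digest": self.database_digest,
            "seed": self.seed,
            "software_version": self.software_version,
            "stage_io_counts": self.stage_io_counts,
            "notes": self.notes,
            "status": self.status,
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")
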