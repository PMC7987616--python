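"""Declarative study designs: the user inputs of the six ETL stages.

A design is a single YAML or JSON document describing the study period and
population filters, the code entities (named bundles of clinical codes with
inclusion/exclusion semantics), the exposure combination logic and parsing
mode, control requirements and matching criteria, outcomes, and baseline
variables. ``StudyDesign.from_file`` validates the whole document and parses
the combination logic up front, so an invalid design fails before any data
is touched.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import (BaseModel, ConfigDict, Field, field_serializer,
                      field_validator, model_validator)

from .dates import parse_date
from . import logic as logic_mod

INCLUSION_TYPES = ("incident_only", "incident_or_prevalent", "first_after_entry")
EXCLUSION_TYPES = ("exclude_ever", "exclude_before_index")


def _coerce_date(v):
    if isinstance(v, dt.date):
        return v
    if isinstance(v, str):
        return parse_date(v, allow_dayfirst=True)
    raise TypeError(f"expected a date, got {v!r}")


class StudyPeriodSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    study_start: dt.date
    study_end: dt.date
    key_date_offset_days: int = Field(0, ge=0)
    registration_leadin_days: int = Field(0, ge=0)
    entry_age_min: int = Field(0, ge=0)
    entry_age_max: int = Field(120, ge=0)
    exit_age_max: int = Field(120, ge=0)
    sex_filter: Literal["male", "female", "any"] = "any"

    _dates = field_validator("study_start", "study_end", mode="before")(_coerce_date)

    @field_validator("sex_filter", mode="before")
    @classmethod
    def _norm_sex(cls, v):
        return v.lower() if isinstance(v, str) else v

    @model_validator(mode="after")
    def _check(self):
        if not self.study_start < self.study_end:
            raise ValueError("study_start must precede study_end")
        if not (self.entry_age_min <= self.entry_age_max <= self.exit_age_max):
            raise ValueError("require entry_age_min <= entry_age_max <= exit_age_max")
        return self


class CodeEntity(BaseModel):
    """A named bundle of clinical codes plus the rule for how its occurrence
    qualifies (inclusion) or disqualifies (exclusion) a patient. Entities
    referenced only as outcomes, baselines or matching variables carry no
    criteria (stages 4-6 ignore them)."""

    model_config = ConfigDict(frozen=True)

    name: str
    criteria: Optional[Literal["inclusion", "exclusion"]] = None
    exposure_type: Optional[str] = None
    definition: frozenset[str]

    @field_validator("definition", mode="before")
    @classmethod
    def _codes(cls, v):
        if isinstance(v, str):
            v = [c.strip() for c in v.split(",") if c.strip()]
        return frozenset(str(c) for c in v)

    @field_serializer("definition")
    def _ser_codes(self, v: frozenset[str]):  # stable order for digests/round-trips
        return sorted(v)

    @model_validator(mode="after")
    def _check(self):
        if not self.definition:
            raise ValueError(f"entity {self.name!r}: definition must be non-empty")
        if self.criteria == "inclusion":
            if self.exposure_type not in INCLUSION_TYPES:
                raise ValueError(
                    f"entity {self.name!r}: inclusion exposure_type must be one of {INCLUSION_TYPES}")
        elif self.criteria == "exclusion":
            if self.exposure_type not in EXCLUSION_TYPES:
                raise ValueError(
                    f"entity {self.name!r}: exclusion exposure_type must be one of {EXCLUSION_TYPES}")
        elif self.exposure_type is not None:
            raise ValueError(f"entity {self.name!r}: exposure_type requires criteria")
        return self


class CombinationLogic(BaseModel):
    model_config = ConfigDict(frozen=True)

    expression: str
    mode: Literal["strict", "loose"] = "loose"

    @field_validator("mode", mode="before")
    @classmethod
    def _norm(cls, v):
        return v.lower() if isinstance(v, str) else v

    @property
    def ast(self) -> logic_mod.Node:
        return logic_mod.parse_logic(self.expression)

    def canonical(self) -> str:
        return logic_mod.to_text(self.ast)


class MeasurementMatch(BaseModel):
    model_config = ConfigDict(frozen=True)
    entity: str
    lookback_days: int = Field(ge=0)
    value_tolerance: float = Field(ge=0)


class DurationMatch(BaseModel):
    model_config = ConfigDict(frozen=True)
    entity: str
    tolerance_days: int = Field(ge=0)


class MatchCriteria(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_controls_per_exposed: int = Field(ge=1)
    age_tolerance_years: int = Field(0, ge=0)
    sex_match: Literal["yes", "any", "opposite"] = "yes"
    registration_tolerance_days: Optional[int] = Field(None, ge=0)
    match_ethnicity: bool = False
    match_townsend: bool = False
    exposure_duration: Optional[DurationMatch] = None
    baseline_conditions: list[str] = Field(default_factory=list)
    baseline_treatments: list[str] = Field(default_factory=list)
    measurement_matches: list[MeasurementMatch] = Field(default_factory=list)
    exclude_outcomes_before_index: list[str] = Field(default_factory=list)
    exclude_events_before_index: list[str] = Field(default_factory=list)
    unmatched_policy: Literal["keep_unmatched", "drop_unmatched"] = "keep_unmatched"

    @field_validator("sex_match", mode="before")
    @classmethod
    def _norm_sex_match(cls, v):
        if v is True:
            return "yes"
        return v.lower() if isinstance(v, str) else v


class BaselineSpec(BaseModel):
    model_config = ConfigDict(frozen=True)
    entity: str
    rule: Literal["latest_before_index", "earliest_ever", "first_after_index"] = "latest_before_index"
    lookback_days: Optional[int] = Field(None, ge=0)


class StudyDesign(BaseModel):
    model_config = ConfigDict(frozen=True)

    design_type: Literal["cohort", "case_control", "cross_sectional"]
    period: StudyPeriodSpec
    entities: list[CodeEntity]
    exposure_logic: CombinationLogic
    control_logic: Optional[CombinationLogic] = None
    controls_required: bool = False
    match_criteria: Optional[MatchCriteria] = None
    outcomes: list[str] = Field(default_factory=list)
    pre_index_outcome_exclusion: bool = False
    baselines: list[BaselineSpec] = Field(default_factory=list)
    seed: int = 0
    encrypt_password: Optional[str] = None

    # -- validation ------------------------------------------------------
    @model_validator(mode="after")
    def _check(self):
        names = [e.name for e in self.entities]
        if len(names) != len(set(names)):
            raise ValueError("entity names must be unique within a design")
        declared = set(names)
        inclusion = {e.name for e in self.entities if e.criteria == "inclusion"}

        for lg, label in ((self.exposure_logic, "exposure_logic"),
                          (self.control_logic, "control_logic")):
            if lg is None:
                continue
            ast = logic_mod.parse_logic(lg.expression)  # syntax errors surface here
            refs = logic_mod.entity_names(ast)
            bad = refs - inclusion
            if bad:
                raise ValueError(
                    f"{label} references entities that are not declared inclusion "
                    f"entities: {sorted(bad)}")

        def _resolve(ref_list, label):
            for r in ref_list:
                if r not in declared:
                    raise ValueError(f"{label} references undeclared entity {r!r}")

        _resolve(self.outcomes, "outcomes")
        _resolve([b.entity for b in self.baselines], "baselines")
        if self.match_criteria is not None:
            mc = self.match_criteria
            refs = (mc.baseline_conditions + mc.baseline_treatments
                    + [m.entity for m in mc.measurement_matches]
                    + mc.exclude_outcomes_before_index + mc.exclude_events_before_index)
            if mc.exposure_duration is not None:
                refs.append(mc.exposure_duration.entity)
            _resolve(refs, "match_criteria")

        if self.design_type == "cross_sectional":
            problems = []
            if self.outcomes:
                problems.append("outcomes must be empty")
            if self.match_criteria is not None:
                problems.append("match_criteria must be absent")
            if self.controls_required:
                problems.append("controls_required must be false")
            if problems:
                raise ValueError(f"cross_sectional design invalid: {'; '.join(problems)}")
        if self.controls_required and self.match_criteria is None:
            raise ValueError("controls_required designs need match_criteria")
        return self

    # -- helpers ---------------------------------------------------------
    def entity(self, name: str) -> CodeEntity:
        for e in self.entities:
            if e.name == name:
                return e
        raise KeyError(name)

    def exclusion_entities(self) -> list[CodeEntity]:
        return [e for e in self.entities if e.criteria == "exclusion"]

    def logic_entities(self, lg: CombinationLogic) -> list[CodeEntity]:
        refs = logic_mod.entity_names(lg.ast)
        return [e for e in self.entities if e.name in refs]

    def digest(self) -> str:
        blob = json.dumps(self.model_dump(mode="json", exclude={"encrypt_password"}),
                          sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyDesign":
        p = Path(path)
        text = p.read_text()
        data = json.loads(text) if p.suffix == ".json" else yaml.safe_load(text)
        return cls.model_validate(data)

    def to_file(self, path: str | Path) -> None:
        data = self.model_dump(mode="json", exclude_none=True)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
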