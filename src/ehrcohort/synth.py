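"""Seeded synthetic-EHR generator with planted epidemiological structure.

The generator emulates a UK-primary-care-like source: practices with
data-quality key dates and a final collection date, patients with a
registration lifecycle (registration, optional deregistration or death),
and coded events. Three planted mechanisms make pipeline recovery testable
without any licensed data:

* **exposure** — a first diagnosis event drawn from a constant per-year
  incidence from registration, with an optional prescription event a fixed
  lag later (exercises strict two-entity sequences);
* **outcome** — a piecewise-exponential first-event clock: constant baseline
  hazard before the patient's first exposure event and baseline x hazard
  ratio afterwards, so the expected extracted rates have closed form;
* **prevalent condition** — an optional Bernoulli point-prevalence planting
  for cross-sectional recovery.

Covariates (Townsend quintile, ethnicity, BMI and HbA1c measurement
streams, smoking status) are sampled independently. Everything is driven by
one seed; generation is reproducible byte-for-byte.
"""
from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import CodedEvent, EHRDatabase, IntegrityReport, PatientRecord, Practice

EPOCH = dt.date(1970, 1, 1)
DAYS_PER_YEAR = 365.25

ETHNICITIES = ("white", "south_asian", "black", "mixed", "other")
ETHNICITY_P = (0.81, 0.08, 0.04, 0.03, 0.04)


class SimConfig(BaseModel):
    """Study conditions for a generated database."""

    model_config = ConfigDict(frozen=True)

    seed: int = 0
    n_practices: int = Field(20, ge=1)
    patients_per_practice: int = Field(1100, ge=1)
    span_start: dt.date = dt.date(2000, 1, 1)
    span_end: dt.date = dt.date(2019, 12, 31)
    female_fraction: float = Field(0.5, ge=0, le=1)
    birth_year_min: int = 1930
    birth_year_max: int = 1995
    registration_lookback_years: float = Field(5.0, ge=0)
    deregistration_rate: float = Field(0.02, ge=0)   # per person-year
    death_rate: float = Field(0.01, ge=0)            # per person-year
    exposure_codes: tuple[str, ...] = ("EXP001",)
    exposure_rx_code: Optional[str] = "EXPRX01"
    exposure_rx_lag_days: int = Field(60, ge=0)
    exposure_incidence_per_year: float = Field(0.012, ge=0)
    outcome_codes: tuple[str, ...] = ("OUT001",)
    outcome_baseline_hazard: float = Field(44e-5, ge=0)  # events per person-year, unexposed
    hazard_ratio: float = Field(3.0, gt=0)
    prevalent_condition_code: Optional[str] = None
    point_prevalence: float = Field(0.033, ge=0, le=1)
    prevalence_reference_date: Optional[dt.date] = None  # plant diagnoses on/before this date
    bmi_rate: float = Field(0.25, ge=0)              # measurements per person-year
    bmi_mean: float = 27.0
    bmi_sd: float = 4.5
    hba1c_rate: float = Field(0.25, ge=0)
    hba1c_mean: float = 42.0
    hba1c_sd: float = 8.0
    smoking_recorded_fraction: float = Field(0.7, ge=0, le=1)
    covariate_missing_fraction: float = Field(0.1, ge=0, le=1)

    @model_validator(mode="after")
    def _check(self):
        if self.span_start >= self.span_end:
            raise ValueError("simulation span is empty")
        if self.birth_year_min > self.birth_year_max:
            raise ValueError("birth-year range is empty")
        return self


def _date(ordinal: float) -> dt.date:
    return EPOCH + dt.timedelta(days=int(ordinal))


def generate(config: SimConfig) -> EHRDatabase:
    """Generate a database realizing the configured study conditions."""
    rng = np.random.default_rng(config.seed)
    span_start = (config.span_start - EPOCH).days
    span_end = (config.span_end - EPOCH).days

    practices: dict[str, Practice] = {}
    practice_ids = []
    for i in range(config.n_practices):
        pid = f"prac{i + 1:03d}"
        key = span_start + int(rng.integers(-3650, 365))
        collection = span_end - int(rng.integers(0, 180))
        practices[pid] = Practice(pid, _date(min(key, collection)), _date(collection))
        practice_ids.append(pid)

    n = config.n_practices * config.patients_per_practice
    sex = np.where(rng.random(n) < config.female_fraction, "female", "male")
    birth_year = rng.integers(config.birth_year_min, config.birth_year_max + 1, size=n)
    birth_doy = rng.integers(0, 365, size=n)
    birth = np.array([(dt.date(int(y), 1, 1) - EPOCH).days for y in birth_year]) + birth_doy

    lookback = config.registration_lookback_years * DAYS_PER_YEAR
    reg = rng.uniform(span_start - lookback, span_end, size=n).astype(np.int64)
    reg = np.maximum(reg, birth)  # nobody registers before birth

    # Lifecycle exits: competing constant-hazard deregistration and death.
    dereg_t = (rng.exponential(1.0 / max(config.deregistration_rate, 1e-12), size=n)
               * DAYS_PER_YEAR + reg if config.deregistration_rate > 0
               else np.full(n, np.inf))
    death_t = (rng.exponential(1.0 / max(config.death_rate, 1e-12), size=n)
               * DAYS_PER_YEAR + reg if config.death_rate > 0
               else np.full(n, np.inf))

    townsend = rng.integers(1, 6, size=n)
    townsend_missing = rng.random(n) < config.covariate_missing_fraction
    ethnicity = rng.choice(ETHNICITIES, size=n, p=ETHNICITY_P)
    ethnicity_missing = rng.random(n) < config.covariate_missing_fraction

    # Planted exposure: first event from a constant per-year incidence.
    if config.exposure_incidence_per_year > 0:
        exp_t = reg + rng.exponential(
            1.0 / config.exposure_incidence_per_year, size=n) * DAYS_PER_YEAR
    else:
        exp_t = np.full(n, np.inf)

    # Piecewise-exponential outcome clock (first event only): baseline
    # hazard before the exposure event, baseline x HR after it.
    lam0 = config.outcome_baseline_hazard / DAYS_PER_YEAR  # per day
    if lam0 > 0:
        first = reg + rng.exponential(1.0 / lam0, size=n)
        needs_switch = first > exp_t
        out_t = np.where(needs_switch, np.inf, first)
        idx = np.nonzero(needs_switch)[0]
        if len(idx):
            lam1 = lam0 * config.hazard_ratio
            out_t[idx] = exp_t[idx] + rng.exponential(1.0 / lam1, size=len(idx))
    else:
        out_t = np.full(n, np.inf)

    prevalent = (rng.random(n) < config.point_prevalence
                 if config.prevalent_condition_code else np.zeros(n, dtype=bool))

    patients: dict[str, PatientRecord] = {}
    events: list[CodedEvent] = []
    exposure_code = config.exposure_codes[0]
    outcome_code = config.outcome_codes[0]
    for i in range(n):
        pid = f"pt{i + 1:06d}"
        practice = practice_ids[i % config.n_practices]
        collection = (practices[practice].collection_date - EPOCH).days
        death = death_t[i] if np.isfinite(death_t[i]) else None
        dereg = dereg_t[i] if np.isfinite(dereg_t[i]) else None
        if death is not None and dereg is not None:
            if death <= dereg:
                dereg = None  # died while registered
            else:
                death = None  # left the practice first; death unobserved
        record_end = min(x for x in (death, dereg, collection) if x is not None)

        patients[pid] = PatientRecord(
            patient_id=pid, practice_id=practice, sex=str(sex[i]),
            birth_date=_date(birth[i]), birth_precision="day",
            registration_date=_date(reg[i]),
            deregistration_date=_date(dereg) if dereg is not None else None,
            death_date=_date(death) if death is not None else None,
            townsend_quintile=None if townsend_missing[i] else int(townsend[i]),
            ethnicity=None if ethnicity_missing[i] else str(ethnicity[i]),
        )

        if exp_t[i] <= record_end:
            ev_date = _date(exp_t[i])
            events.append(CodedEvent(pid, exposure_code, ev_date, table_of_origin="clinical"))
            if config.exposure_rx_code is not None:
                rx = exp_t[i] + config.exposure_rx_lag_days
                if rx <= record_end:
                    events.append(CodedEvent(pid, config.exposure_rx_code, _date(rx),
                                             table_of_origin="therapy"))
        if out_t[i] <= record_end:
            events.append(CodedEvent(pid, outcome_code, _date(out_t[i]),
                                     table_of_origin="clinical"))
        if prevalent[i]:
            upper = record_end
            if config.prevalence_reference_date is not None:
                upper = min(upper, (config.prevalence_reference_date - EPOCH).days)
            d = rng.uniform(reg[i], upper) if upper > reg[i] else reg[i]
            events.append(CodedEvent(pid, config.prevalent_condition_code, _date(d),
                                     table_of_origin="clinical"))

        obs_years = max(record_end - reg[i], 0) / DAYS_PER_YEAR
        for code, rate, mean, sd, unit in (
            ("BMI001", config.bmi_rate, config.bmi_mean, config.bmi_sd, "kg/m2"),
            ("HBA1C01", config.hba1c_rate, config.hba1c_mean, config.hba1c_sd, "mmol/mol"),
        ):
            if rate <= 0 or obs_years <= 0:
                continue
            k = rng.poisson(rate * obs_years)
            if k == 0:
                continue
            days = np.sort(rng.uniform(reg[i], record_end, size=k))
            values = rng.normal(mean, sd, size=k)
            for d, v in zip(days, values):
                events.append(CodedEvent(pid, code, _date(d), float(round(v, 1)),
                                         unit, "measurement"))
        if rng.random() < config.smoking_recorded_fraction and obs_years > 0:
            d = rng.uniform(reg[i], record_end)
            code = "SMOK01" if rng.random() < 0.25 else "SMOK00"  # smoker / never
            events.append(CodedEvent(pid, code, _date(d), table_of_origin="clinical"))

    return EHRDatabase(practices, patients, events, IntegrityReport())


# ---------------------------------------------------------------------------
# Worked toy fixture
# ---------------------------------------------------------------------------

def _p(pid, prac, sex, birth, reg, dereg=None, death=None, townsend=None,
       ethnicity=None, precision="day"):
    return PatientRecord(
        patient_id=pid, practice_id=prac, sex=sex,
        birth_date=dt.date.fromisoformat(birth), birth_precision=precision,
        registration_date=dt.date.fromisoformat(reg),
        deregistration_date=dt.date.fromisoformat(dereg) if dereg else None,
        death_date=dt.date.fromisoformat(death) if death else None,
        townsend_quintile=townsend, ethnicity=ethnicity)


def _e(pid, code, date, value=None, table="clinical", unit=None):
    return CodedEvent(pid, code, dt.date.fromisoformat(date), value, unit, table)


def worked_toy() -> EHRDatabase:
    """A small fixed database exercising every pipeline edge case.

    Three practices and forty patients, constructed by hand: it contains
    prevalent exposure at entry, an out-of-order strict sequence, pre-index
    outcomes, a year-precision birth date, an unmatched exposed patient,
    deaths and deregistrations, and measurement streams for baseline
    extraction. Deterministic: repeated calls build the identical database.
    """
    practices = {
        "pracA": Practice("pracA", dt.date(1996, 3, 1), dt.date(2018, 5, 1)),
        "pracB": Practice("pracB", dt.date(2001, 9, 15), dt.date(2019, 11, 30)),
        # pracC's collection predates the study window entirely
        "pracC": Practice("pracC", dt.date(1990, 1, 1), dt.date(1996, 6, 30)),
    }
    patients = [
        # --- pracA ---------------------------------------------------
        # exposed, clean diabetes -> metformin sequence, one outcome
        _p("pt001", "pracA", "female", "1955-04-12", "1999-02-01", townsend=2, ethnicity="white"),
        # exposed, same-day diagnosis + prescription (in-order under <=)
        _p("pt002", "pracA", "male", "1948-11-30", "1998-07-15", townsend=4, ethnicity="white"),
        # strict-order violation: metformin before diabetes
        _p("pt003", "pracA", "male", "1960-01-20", "2000-03-01", townsend=3),
        # prevalent diabetes before patient start (incident-only rejection)
        _p("pt004", "pracA", "female", "1950-06-05", "2004-01-10", townsend=1, ethnicity="black"),
        # exposed but stroke before index -> pre-index outcome exclusion
        _p("pt005", "pracA", "female", "1952-09-01", "1999-05-20", townsend=2, ethnicity="white"),
        # control candidates
        _p("pt006", "pracA", "female", "1955-08-23", "1999-01-05", townsend=2, ethnicity="white"),
        _p("pt007", "pracA", "female", "1956-02-17", "2000-06-01", townsend=5, ethnicity="south_asian"),
        _p("pt008", "pracA", "male", "1949-03-02", "1998-04-18", townsend=4, ethnicity="white"),
        _p("pt009", "pracA", "male", "1947-12-25", "2001-02-02", townsend=3, ethnicity="white"),
        # dies during follow-up
        _p("pt010", "pracA", "female", "1954-10-10", "1999-09-09", death="2012-03-04", townsend=2),
        # deregisters early
        _p("pt011", "pracA", "male", "1958-05-06", "2000-01-01", dereg="2006-06-30", townsend=1),
        # year-precision birth date (anchored to July 1)
        _p("pt012", "pracA", "female", "1953-07-01", "2000-11-11", townsend=2,
           ethnicity="white", precision="year"),
        # too old at entry (born 1920: age 80+ at patient start, cap 75)
        _p("pt013", "pracA", "male", "1920-02-29", "1998-01-01", townsend=3),
        # registered after collection window closes -> no overlap
        _p("pt014", "pracA", "male", "1965-03-15", "2018-04-30", townsend=4),
        # too young: attains 40 only after practice end
        _p("pt015", "pracA", "female", "1990-01-01", "2005-05-05", townsend=5),
        _p("pt016", "pracA", "female", "1957-01-09", "2002-08-08", townsend=2, ethnicity="mixed"),
        _p("pt017", "pracA", "male", "1951-06-21", "1999-10-30", townsend=3, ethnicity="white"),
        # exposure ever-recorded exclusion (amputation code)
        _p("pt018", "pracA", "male", "1950-04-04", "1998-12-12", townsend=3, ethnicity="white"),
        _p("pt019", "pracA", "female", "1949-11-02", "1999-03-03", townsend=1, ethnicity="white"),
        _p("pt020", "pracA", "male", "1962-07-19", "2001-01-25", townsend=2, ethnicity="white"),
        # --- pracB ---------------------------------------------------
        # exposed late in window; few candidate controls of same age -> may go unmatched
        _p("pt021", "pracB", "female", "1935-02-03", "2002-01-01", townsend=4, ethnicity="white"),
        # exposed male
        _p("pt022", "pracB", "male", "1957-08-14", "2002-02-02", townsend=2, ethnicity="white"),
        _p("pt023", "pracB", "male", "1958-03-29", "2002-05-05", townsend=2, ethnicity="white"),
        _p("pt024", "pracB", "male", "1956-09-09", "2003-03-03", townsend=4, ethnicity="white"),
        _p("pt025", "pracB", "female", "1943-12-01", "2002-04-04", townsend=5, ethnicity="black"),
        _p("pt026", "pracB", "female", "1944-06-06", "2002-09-01", townsend=3, ethnicity="white"),
        # diabetes after patient end (not exposed)
        _p("pt027", "pracB", "male", "1955-05-15", "2002-03-14", dereg="2008-08-08", townsend=2),
        # female, dies before any event
        _p("pt028", "pracB", "female", "1940-01-31", "2002-06-20", death="2005-10-01", townsend=1),
        _p("pt029", "pracB", "male", "1959-04-01", "2003-01-17", townsend=2, ethnicity="south_asian"),
        _p("pt030", "pracB", "female", "1942-10-22", "2002-11-05", townsend=4, ethnicity="white"),
        # male excluded by sex in the female-only variant designs; normal control here
        _p("pt031", "pracB", "male", "1954-02-11", "2004-04-09", townsend=3, ethnicity="white"),
        _p("pt032", "pracB", "female", "1936-05-27", "2002-07-07", townsend=2, ethnicity="white"),
        # incident-or-prevalent entity user: diabetes before start but design is incident-only
        _p("pt033", "pracB", "male", "1950-10-05", "2006-01-01", townsend=5, ethnicity="other"),
        _p("pt034", "pracB", "female", "1938-08-18", "2003-02-28", townsend=4, ethnicity="white"),
        _p("pt035", "pracB", "male", "1961-01-07", "2002-12-24", townsend=1, ethnicity="white"),
        _p("pt036", "pracB", "female", "1945-03-30", "2004-06-15", townsend=3, ethnicity="white"),
        # --- pracC (practice outside study period) -------------------
        _p("pt037", "pracC", "male", "1950-01-01", "1991-01-01", townsend=2),
        _p("pt038", "pracC", "female", "1955-02-02", "1992-02-02", townsend=3),
        # --- more pracA edge material --------------------------------
        _p("pt039", "pracA", "female", "1953-03-03", "1999-06-06", townsend=2, ethnicity="white"),
        _p("pt040", "pracA", "male", "1959-09-23", "2000-04-12", townsend=4, ethnicity="white"),
    ]
    events = [
        # pt001: diabetes 2005, metformin 2007 (index 2007-06-15), IHD 2010
        _e("pt001", "C10F.00", "2005-03-01"),
        _e("pt001", "MFN001", "2007-06-15", table="therapy"),
        _e("pt001", "IHD001", "2010-02-10"),
        _e("pt001", "BMI001", "2006-01-20", value=31.5, table="measurement", unit="kg/m2"),
        _e("pt001", "BMI001", "2007-05-30", value=30.2, table="measurement", unit="kg/m2"),
        _e("pt001", "SMOK01", "2003-03-03"),
        # pt002: same-day diagnosis + prescription
        _e("pt002", "C10F.11", "2006-09-10"),
        _e("pt002", "MFN001", "2006-09-10", table="therapy"),
        _e("pt002", "BMI001", "2002-02-02", value=28.0, table="measurement", unit="kg/m2"),
        # pt003: metformin 2004 before diabetes 2008 -> strict rejection
        _e("pt003", "MFN001", "2004-04-04", table="therapy"),
        _e("pt003", "C10F.00", "2008-08-08"),
        # pt004: prevalent diabetes (1995, well before any possible start)
        _e("pt004", "C10F.00", "1995-05-05"),
        _e("pt004", "MFN001", "2006-06-06", table="therapy"),
        # pt005: diabetes+metformin but stroke one day before index
        _e("pt005", "C10F.00", "2004-02-01"),
        _e("pt005", "MFN001", "2006-03-15", table="therapy"),
        _e("pt005", "STRK01", "2006-03-14"),
        # pt006: healthy control with BMI history
        _e("pt006", "BMI001", "2005-12-01", value=26.4, table="measurement", unit="kg/m2"),
        _e("pt006", "SMOK00", "2001-01-01"),
        # pt007: control, hypertension at baseline
        _e("pt007", "HTN001", "2003-04-05"),
        # pt008: control with later stroke (fine: outcome after index for its group)
        _e("pt008", "STRK01", "2014-09-01"),
        # pt009: control
        _e("pt009", "BMI001", "2006-11-11", value=24.9, table="measurement", unit="kg/m2"),
        # pt010: control who dies 2012
        _e("pt010", "BMI001", "2007-01-05", value=29.7, table="measurement", unit="kg/m2"),
        # pt012: year-precision birth; diabetes 2009, metformin 2009 later
        _e("pt012", "C10F.00", "2009-02-14"),
        _e("pt012", "MFN001", "2009-10-01", table="therapy"),
        _e("pt012", "HF0001", "2015-07-07"),
        # pt017: control with IHD before typical index dates (exercises
        # matching-stage outcome exclusion)
        _e("pt017", "IHD001", "2004-01-01"),
        # pt018: diabetes+metformin but amputation ever -> excluded
        _e("pt018", "C10F.00", "2005-01-01"),
        _e("pt018", "MFN001", "2006-01-01", table="therapy"),
        _e("pt018", "AMP001", "2016-10-10"),
        # pt021: exposed elderly female
        _e("pt021", "C10F.00", "2006-04-01"),
        _e("pt021", "MFN001", "2008-03-20", table="therapy"),
        _e("pt021", "STRK01", "2013-11-23"),
        # pt022: exposed male with heart failure outcome
        _e("pt022", "C10F.11", "2007-07-07"),
        _e("pt022", "MFN001", "2009-01-30", table="therapy"),
        _e("pt022", "HF0001", "2016-02-18"),
        _e("pt022", "BMI001", "2008-12-25", value=33.1, table="measurement", unit="kg/m2"),
        # pt023/024: male controls near pt022's age
        _e("pt023", "BMI001", "2008-10-01", value=27.7, table="measurement", unit="kg/m2"),
        _e("pt024", "SMOK01", "2005-05-05"),
        # pt027: diabetes recorded after deregistration (outside window)
        _e("pt027", "C10F.00", "2012-01-01"),
        # pt033: diabetes before start (registered 2006, diagnosis 2003)
        _e("pt033", "C10F.00", "2003-03-03"),
        _e("pt033", "MFN001", "2007-02-02", table="therapy"),
        # pt035: only metformin, never diabetes -> logic unsatisfied
        _e("pt035", "MFN001", "2005-09-09", table="therapy"),
        # pt039: control with measurements
        _e("pt039", "BMI001", "2006-06-01", value=30.9, table="measurement", unit="kg/m2"),
        _e("pt039", "SMOK00", "2004-08-08"),
        # pt040: control
        _e("pt040", "BMI001", "2005-04-04", value=25.5, table="measurement", unit="kg/m2"),
    ]
    return EHRDatabase(practices, {p.patient_id: p for p in patients}, events,
                       IntegrityReport())


def worked_toy_design() -> dict:
    """The documented study design used with :func:`worked_toy` (as plain
    data, ready for ``StudyDesign.model_validate`` or YAML serialization).

    A matched cohort: incident type-2 diabetes followed by metformin
    (strict order, same-day allowed), two age/sex-matched controls per
    exposed sharing the exposed patient's index date, cardiovascular
    outcomes, pre-index outcome exclusion on both arms, BMI and smoking at
    baseline.
    """
    return {
        "design_type": "cohort",
        "period": {
            "study_start": "1998-01-15",
            "study_end": "2019-12-15",
            "key_date_offset_days": 365,
            "registration_leadin_days": 365,
            "entry_age_min": 40,
            "entry_age_max": 75,
            "exit_age_max": 90,
            "sex_filter": "any",
        },
        "entities": [
            {"name": "Type2Diabetes", "criteria": "inclusion",
             "exposure_type": "incident_only", "definition": ["C10F.00", "C10F.11"]},
            {"name": "Metformin", "criteria": "inclusion",
             "exposure_type": "incident_only", "definition": ["MFN001"]},
            {"name": "Amputation", "criteria": "exclusion",
             "exposure_type": "exclude_ever", "definition": ["AMP001"]},
            {"name": "IschemicHeartDisease", "definition": ["IHD001"]},
            {"name": "Stroke", "definition": ["STRK01"]},
            {"name": "HeartFailure", "definition": ["HF0001"]},
            {"name": "BMI", "definition": ["BMI001"]},
            {"name": "Smoking", "definition": ["SMOK00", "SMOK01"]},
        ],
        "exposure_logic": {"expression": "Type2Diabetes and Metformin", "mode": "strict"},
        "controls_required": True,
        "match_criteria": {
            "n_controls_per_exposed": 2,
            "age_tolerance_years": 5,
            "sex_match": "yes",
            "exclude_outcomes_before_index": ["IschemicHeartDisease", "Stroke",
                                              "HeartFailure"],
        },
        "outcomes": ["IschemicHeartDisease", "Stroke", "HeartFailure"],
        "pre_index_outcome_exclusion": True,
        "baselines": [
            {"entity": "BMI", "rule": "latest_before_index", "lookback_days": 735},
            {"entity": "Smoking", "rule": "latest_before_index"},
        ],
        "seed": 20240101,
    }
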