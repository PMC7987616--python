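"""Stage 6 — baseline variables, dataset assembly and summary epidemiology.

Baseline extraction is a simple per-patient lookup governed by a retrieval
rule (latest value on or before index within an optional lookback, earliest
ever, or first after index). Assembly produces one wide row per surviving
member with a deterministic column order, so identical inputs yield
byte-identical CSV output. The summary helpers compute incidence rates per
100,000 person-years with exact Poisson confidence intervals and point
prevalence with exact (Clopper-Pearson) binomial intervals, optionally
stratified by sex, age band, exposure group, or calendar year (person-time
is split across years for yearly incidence).
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dates import age_in_years, fmt
from .design import BaselineSpec, StudyDesign
from .model import EHRDatabase
from .stage1 import CohortMember, ROLE_EXPOSED
from .stage4 import MatchedSet

DAYS_PER_YEAR = 365.25


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def extract_baseline(
    member: CohortMember, spec: BaselineSpec, db: EHRDatabase, design: StudyDesign
) -> tuple[Optional[float], Optional[dt.date]]:
    """(value, date) of the baseline variable, or (None, None) when absent.

    Valued (measurement) entities return the event value; coded diagnosis or
    treatment entities return value ``None`` with the event date as the
    presence marker.
    """
    codes = design.entity(spec.entity).definition
    pid = member.patient_id
    if spec.rule == "earliest_ever":
        ev = db.first_event(pid, codes)
    elif spec.rule == "first_after_index":
        ev = db.first_event(pid, codes, not_before=member.index_date + dt.timedelta(days=1))
    else:  # latest_before_index
        if member.index_date is None:
            return None, None
        start = dt.date.min
        if spec.lookback_days is not None:
            start = member.index_date - dt.timedelta(days=spec.lookback_days)
        ev = None
        for cand in db.events_for(pid, codes, (start, member.index_date)):
            ev = cand  # ascending: keep the latest
    if ev is None:
        return None, None
    return ev.value, ev.event_date


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def dataset_columns(design: StudyDesign) -> list[str]:
    cols = ["patient_id", "practice_id"]
    if design.design_type != "cross_sectional":
        cols += ["group_id", "exposed_flag", "match_order"]
    else:
        cols += ["exposed_flag"]
    cols += ["sex", "age_at_index", "townsend_quintile", "ethnicity",
             "index_date", "patient_start", "patient_end"]
    if design.design_type != "cross_sectional":
        cols += ["exit_date", "follow_up_days"]
        for name in design.outcomes:
            cols += [f"{name}_event", f"{name}_date", f"{name}_days"]
    for b in design.baselines:
        cols += [f"{b.entity}_value", f"{b.entity}_date"]
    return cols


def assemble(
    members: Sequence[CohortMember],
    design: StudyDesign,
    db: EHRDatabase,
    matched_sets: Optional[Sequence[MatchedSet]] = None,
) -> pd.DataFrame:
    """One analysable row per surviving member, deterministically ordered.

    Cohort/case-control rows sort by (group id, exposed first, match order);
    cross-sectional rows sort by patient id. Missing values are empty
    strings in the CSV form, mirroring the input convention.
    """
    for member in members:
        for bspec in design.baselines:
            member.baselines[bspec.entity] = extract_baseline(member, bspec, db, design)

    cross = design.design_type == "cross_sectional"
    rows = []
    for m in members:
        rec = db.patients[m.patient_id]
        exposed_flag = 1 if m.role == ROLE_EXPOSED else 0
        row: dict = {
            "patient_id": m.patient_id,
            "practice_id": m.practice_id,
            "exposed_flag": exposed_flag,
            "sex": rec.sex,
            "age_at_index": (age_in_years(rec.birth_date, m.index_date)
                             if m.index_date is not None else None),
            "townsend_quintile": rec.townsend_quintile,
            "ethnicity": rec.ethnicity,
            "index_date": fmt(m.index_date),
            "patient_start": fmt(m.window.patient_start),
            "patient_end": fmt(m.window.patient_end),
        }
        if not cross:
            row["group_id"] = m.group_id
            row["match_order"] = m.match_order
            row["exit_date"] = fmt(m.exit_date)
            row["follow_up_days"] = ((m.exit_date - m.index_date).days
                                     if m.exit_date is not None and m.index_date is not None
                                     else None)
            for name in design.outcomes:
                date = m.outcome_dates.get(name)
                row[f"{name}_event"] = 0 if date is None else 1
                row[f"{name}_date"] = fmt(date)
                row[f"{name}_days"] = (date - m.index_date).days if date is not None else None
        for bspec in design.baselines:
            value, date = m.baselines.get(bspec.entity, (None, None))
            row[f"{bspec.entity}_value"] = value
            row[f"{bspec.entity}_date"] = fmt(date)
        rows.append(row)

    df = pd.DataFrame(rows, columns=dataset_columns(design))
    if cross:
        df = df.sort_values("patient_id", kind="mergesort")
    elif len(df):
        df = df.sort_values(
            ["group_id", "exposed_flag", "match_order", "patient_id"],
            ascending=[True, False, True, True], kind="mergesort", na_position="first")
    return df.reset_index(drop=True)


def write_dataset(df: pd.DataFrame, path) -> bytes:
    """Serialize to CSV bytes (missing -> empty field) and write when a
    path is given; returns the bytes either way."""
    out = df.to_csv(index=False, na_rep="").encode()
    if path is not None:
        with open(path, "wb") as fh:
            fh.write(out)
    return out


# ---------------------------------------------------------------------------
# Summary epidemiology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SummaryStats:
    stratum: dict
    events: int
    person_years: float
    rate_per_100k: Optional[float]
    rate_ci_low: Optional[float]
    rate_ci_high: Optional[float]


def poisson_exact_ci(events: int, person_years: float, level: float = 0.95
                     ) -> tuple[float, float]:
    """Exact (chi-square based) CI for a Poisson rate, per 100,000 p-y."""
    alpha = 1 - level
    if person_years <= 0:
        raise ValueError("zero person-years: rate undefined")
    low = 0.0 if events == 0 else stats.chi2.ppf(alpha / 2, 2 * events) / 2
    high = stats.chi2.ppf(1 - alpha / 2, 2 * events + 2) / 2
    scale = 100_000 / person_years
    return low * scale, high * scale


def binomial_exact_ci(cases: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson interval for a proportion."""
    alpha = 1 - level
    low = 0.0 if cases == 0 else stats.beta.ppf(alpha / 2, cases, n - cases + 1)
    high = 1.0 if cases == n else stats.beta.ppf(1 - alpha / 2, cases + 1, n - cases)
    return float(low), float(high)


def _event_and_time(df: pd.DataFrame, outcome: Optional[str]) -> tuple[pd.Series, pd.Series]:
    if outcome is None:  # first of ANY outcome; follow-up already ends at exit
        event_cols = [c for c in df.columns if c.endswith("_event")]
        if not event_cols:
            raise ValueError("dataset has no outcome columns")
        # an event ended follow-up iff some outcome date equals the exit date
        event = pd.Series(False, index=df.index)
        for dc in (c[:-6] + "_date" for c in event_cols):
            event |= (df[dc].astype(str) == df["exit_date"].astype(str)) & (df[dc].astype(str) != "")
        time_days = df["follow_up_days"].astype(float)
        return event, time_days
    event = df[f"{outcome}_event"].astype(float) > 0
    days = df[f"{outcome}_days"]
    end = (pd.to_datetime(df["patient_end"]) - pd.to_datetime(df["index_date"])).dt.days
    time_days = days.where(event, end).astype(float)
    return event, time_days


def _strata_frame(df: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    for key in by:
        if key == "sex":
            out["sex"] = df["sex"]
        elif key == "exposed":
            out["exposed"] = df["exposed_flag"].astype(int)
        elif key == "ageband":
            age = pd.to_numeric(df["age_at_index"], errors="coerce")
            band = (age // 10 * 10).astype("Int64")
            out["ageband"] = band.map(lambda b: f"{b}-{b + 9}" if pd.notna(b) else "unknown")
        elif key == "year":
            pass  # handled by person-time splitting
        else:
            raise ValueError(f"unknown stratifier {key!r}")
    return out


def summarise_incidence(
    df: pd.DataFrame,
    outcome: Optional[str] = None,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Incidence rates per 100,000 person-years with exact Poisson 95% CIs.

    ``by`` may contain "exposed", "sex", "ageband" and/or "year"; the year
    stratifier splits each patient's follow-up across calendar years and
    assigns the event to the year it occurred in.
    """
    if df.empty:
        return pd.DataFrame(columns=[*by, "events", "person_years",
                                     "rate_per_100k", "ci_low", "ci_high"])
    event, time_days = _event_and_time(df, outcome)
    strata = _strata_frame(df, by)
    yearly = "year" in by
    records = []
    if yearly:
        index = pd.to_datetime(df["index_date"]).dt.date
        exit_or_end = (pd.to_datetime(df["exit_date"]) if outcome is None
                       else pd.to_datetime(df["index_date"]) + pd.to_timedelta(time_days, unit="D"))
        exit_or_end = exit_or_end.dt.date
        event_year = pd.Series(
            [None if not e else (s + dt.timedelta(days=int(t))).year
             for e, s, t in zip(event, index, time_days)], index=df.index)
        for i in df.index:
            start, stop = index[i], exit_or_end[i]
            for year in range(start.year, stop.year + 1):
                seg_start = max(start, dt.date(year, 1, 1))
                seg_stop = min(stop, dt.date(year + 1, 1, 1))  # half-open segment
                days = (seg_stop - seg_start).days
                records.append({
                    **({} if strata.empty else strata.loc[i].to_dict()),
                    "year": year,
                    "py": max(days, 0) / DAYS_PER_YEAR,
                    "event": 1 if (event[i] and event_year[i] == year) else 0,
                })
        agg = pd.DataFrame(records)
        keys = [c for c in agg.columns if c not in ("py", "event")]
    else:
        agg = strata.copy()
        agg["py"] = time_days / DAYS_PER_YEAR
        agg["event"] = event.astype(int)
        keys = list(strata.columns)

    if keys:
        grouped = agg.groupby(keys, dropna=False)[["py", "event"]].sum().reset_index()
    else:
        grouped = pd.DataFrame([{"py": agg["py"].sum(), "event": agg["event"].sum()}])

    out_rows = []
    for _, row in grouped.iterrows():
        events_n = int(row["event"])
        py = float(row["py"])
        rec = {k: row[k] for k in keys}
        rec["events"] = events_n
        rec["person_years"] = py
        if py > 0:
            low, high = poisson_exact_ci(events_n, py)
            rec["rate_per_100k"] = events_n / py * 100_000
            rec["ci_low"], rec["ci_high"] = low, high
        else:
            rec["rate_per_100k"] = rec["ci_low"] = rec["ci_high"] = np.nan
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def summarise_prevalence(
    df: pd.DataFrame,
    reference_date: dt.date,
    by: Sequence[str] = (),
) -> pd.DataFrame:
    """Point prevalence on a reference date with exact binomial 95% CIs.

    Denominator: members observed (registered) on the reference date;
    numerator: those exposed with an index date on or before it.
    """
    start = pd.to_datetime(df["patient_start"]).dt.date
    end = pd.to_datetime(df["patient_end"]).dt.date
    present = (start <= reference_date) & (end >= reference_date)
    idx = pd.to_datetime(df["index_date"], errors="coerce").dt.date
    case = (df["exposed_flag"].astype(int) == 1) & idx.notna() & (idx <= reference_date)

    sub = df[present]
    case = case[present]
    strata = _strata_frame(sub, [k for k in by if k != "year"])
    agg = strata.copy()
    agg["case"] = case.astype(int)
    keys = list(strata.columns)
    if keys:
        grouped = agg.groupby(keys, dropna=False)["case"].agg(["sum", "count"]).reset_index()
    else:
        grouped = pd.DataFrame([{"sum": int(agg["case"].sum()), "count": len(agg)}])
    rows = []
    for _, row in grouped.iterrows():
        cases, n = int(row["sum"]), int(row["count"])
        rec = {k: row[k] for k in keys}
        rec["reference_date"] = reference_date.isoformat()
        rec["cases"], rec["population"] = cases, n
        if n:
            low, high = binomial_exact_ci(cases, n)
            rec["prevalence"] = cases / n
            rec["ci_low"], rec["ci_high"] = low, high
        else:
            rec["prevalence"] = rec["ci_low"] = rec["ci_high"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
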