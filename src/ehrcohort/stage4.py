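"""Stage 4 — randomized without-replacement selection of matched controls.

Both the exposed list and the potential-control pool are shuffled with the
seeded generator; a single greedy pass over the shuffled exposed then
filters the remaining pool through the full criterion set, samples
uniformly without replacement, copies the exposed patient's index date onto
the selected controls (avoiding immortal time bias) and assigns consecutive
group ids. Controls are removed from the pool as they are selected, so no
control serves two exposed patients.

Demographic criteria (sex, window coverage of the index date, age, Townsend,
ethnicity, registration date) are evaluated vectorized over the whole pool;
event-dependent criteria (exposure duration, baseline conditions and
treatments, measurement values, pre-index outcome/event exclusions) are then
checked per surviving candidate.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .audit import RejectionLog
from .design import MatchCriteria, StudyDesign
from .model import EHRDatabase
from .stage1 import CohortMember, ROLE_MATCHED_CONTROL

R_NOT_SELECTED = "control not selected"
R_NO_ELIGIBLE = "no eligible controls"


@dataclass(frozen=True)
class MatchedSet:
    group_id: int
    exposed_id: str
    control_ids: tuple[str, ...]
    index_date: dt.date


@dataclass
class _PoolIndex:
    """Column arrays over the potential-control pool for vectorized
    prefiltering; ``available`` implements without-replacement removal."""

    members: list[CohortMember]
    sex: np.ndarray            # 0 = male, 1 = female
    birth_key: np.ndarray      # year*10000 + month*100 + day
    birth_year: np.ndarray
    birth_md: np.ndarray       # month*100 + day
    start_ord: np.ndarray
    end_ord: np.ndarray
    reg_ord: np.ndarray
    townsend: np.ndarray       # -1 = missing
    ethnicity: np.ndarray      # category code, -1 = missing
    eth_codes: dict[str, int]
    available: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.available is None:
            self.available = np.ones(len(self.members), dtype=bool)


def _build_pool_index(pool: Sequence[CohortMember], db: EHRDatabase) -> _PoolIndex:
    n = len(pool)
    sex = np.empty(n, dtype=np.int8)
    birth_year = np.empty(n, dtype=np.int32)
    birth_md = np.empty(n, dtype=np.int32)
    start_ord = np.empty(n, dtype=np.int64)
    end_ord = np.empty(n, dtype=np.int64)
    reg_ord = np.empty(n, dtype=np.int64)
    townsend = np.empty(n, dtype=np.int16)
    ethnicity = np.empty(n, dtype=np.int32)
    eth_codes: dict[str, int] = {}
    for i, m in enumerate(pool):
        rec = db.patients[m.patient_id]
        sex[i] = 0 if rec.sex == "male" else 1
        birth_year[i] = rec.birth_date.year
        birth_md[i] = rec.birth_date.month * 100 + rec.birth_date.day
        start_ord[i] = m.window.patient_start.toordinal()
        end_ord[i] = m.window.patient_end.toordinal()
        reg_ord[i] = rec.registration_date.toordinal()
        townsend[i] = -1 if rec.townsend_quintile is None else rec.townsend_quintile
        if rec.ethnicity is None:
            ethnicity[i] = -1
        else:
            ethnicity[i] = eth_codes.setdefault(rec.ethnicity, len(eth_codes))
    return _PoolIndex(
        members=list(pool), sex=sex,
        birth_key=birth_year * 10000 + birth_md,
        birth_year=birth_year, birth_md=birth_md,
        start_ord=start_ord, end_ord=end_ord, reg_ord=reg_ord,
        townsend=townsend, ethnicity=ethnicity, eth_codes=eth_codes,
    )


def _age_at(index_date: dt.date, birth_year: np.ndarray, birth_md: np.ndarray) -> np.ndarray:
    idx_md = index_date.month * 100 + index_date.day
    return (index_date.year - birth_year) - (idx_md < birth_md)


def _latest_value_in_lookback(db, pid, codes, index_date, lookback_days):
    """Latest (value, date) of a measurement entity on or before index,
    within the lookback window when given."""
    start = dt.date.min if lookback_days is None else index_date - dt.timedelta(days=lookback_days)
    best = None
    for ev in db.events_for(pid, codes, (max(start, dt.date.min), index_date)):
        if ev.value is not None:
            best = ev  # events_for is date-ascending: last wins
    return best


def _candidate_passes_event_criteria(
    exposed: CohortMember,
    candidate: CohortMember,
    criteria: MatchCriteria,
    design: StudyDesign,
    db: EHRDatabase,
) -> bool:
    idx = exposed.index_date
    pid = candidate.patient_id

    if criteria.exposure_duration is not None:
        spec = criteria.exposure_duration
        codes = design.entity(spec.entity).definition
        exp_first = db.first_event(exposed.patient_id, codes, not_after=idx)
        cand_first = db.first_event(pid, codes, not_after=idx)
        if exp_first is None or cand_first is None:
            return False
        dur_exp = (idx - exp_first.event_date).days
        dur_cand = (idx - cand_first.event_date).days
        if abs(dur_cand - dur_exp) > spec.tolerance_days:
            return False

    for names in (criteria.baseline_treatments, criteria.baseline_conditions):
        for name in names:
            codes = design.entity(name).definition
            exp_has = db.first_event(exposed.patient_id, codes, not_after=idx) is not None
            cand_has = db.first_event(pid, codes, not_after=idx) is not None
            if exp_has != cand_has:
                return False

    for mm in criteria.measurement_matches:
        codes = design.entity(mm.entity).definition
        exp_ev = _latest_value_in_lookback(db, exposed.patient_id, codes, idx, mm.lookback_days)
        if exp_ev is None:
            continue  # vacuous when the exposed has no qualifying value
        cand_ev = _latest_value_in_lookback(db, pid, codes, idx, mm.lookback_days)
        if cand_ev is None or abs(cand_ev.value - exp_ev.value) > mm.value_tolerance:
            return False

    for name in criteria.exclude_outcomes_before_index + criteria.exclude_events_before_index:
        codes = design.entity(name).definition
        if db.first_event(pid, codes, not_after=idx) is not None:
            return False
    return True


def eligible_controls(
    exposed: CohortMember,
    pool: Sequence[CohortMember],
    criteria: MatchCriteria,
    db: EHRDatabase,
    design: Optional[StudyDesign] = None,
    _index: Optional[_PoolIndex] = None,
) -> list[CohortMember]:
    """All pool members satisfying every matching criterion for ``exposed``.

    Missing Townsend/ethnicity matches only missing when that criterion is
    on. ``design`` is required when the criteria include event-dependent
    filters (duration, baselines, measurements, pre-index exclusions).
    """
    pix = _index if _index is not None else _build_pool_index(pool, db)
    idx = exposed.index_date
    exp_rec = db.patients[exposed.patient_id]
    mask = pix.available.copy()

    if criteria.sex_match != "any":
        exp_sex = 0 if exp_rec.sex == "male" else 1
        want = exp_sex if criteria.sex_match == "yes" else 1 - exp_sex
        mask &= pix.sex == want

    idx_ord = idx.toordinal()
    mask &= (pix.start_ord <= idx_ord) & (pix.end_ord >= idx_ord)

    from .dates import age_in_years

    exp_age = age_in_years(exp_rec.birth_date, idx)
    ages = _age_at(idx, pix.birth_year, pix.birth_md)
    mask &= np.abs(ages - exp_age) <= criteria.age_tolerance_years

    if criteria.match_townsend:
        exp_t = -1 if exp_rec.townsend_quintile is None else exp_rec.townsend_quintile
        mask &= pix.townsend == exp_t
    if criteria.match_ethnicity:
        if exp_rec.ethnicity is None:
            mask &= pix.ethnicity == -1
        else:
            code = pix.eth_codes.get(exp_rec.ethnicity, -2)
            mask &= pix.ethnicity == code
    if criteria.registration_tolerance_days is not None:
        exp_reg = exp_rec.registration_date.toordinal()
        mask &= np.abs(pix.reg_ord - exp_reg) <= criteria.registration_tolerance_days

    needs_events = (
        criteria.exposure_duration is not None or criteria.baseline_conditions
        or criteria.baseline_treatments or criteria.measurement_matches
        or criteria.exclude_outcomes_before_index or criteria.exclude_events_before_index
    )
    out: list[CohortMember] = []
    for i in np.nonzero(mask)[0]:
        cand = pix.members[i]
        if needs_events:
            if design is None:
                raise ValueError("event-dependent matching criteria need the study design")
            if not _candidate_passes_event_criteria(exposed, cand, criteria, design, db):
                continue
        out.append(cand)
    return out


def run_stage4(
    exposed_list: list[CohortMember],
    pool: list[CohortMember],
    criteria: MatchCriteria,
    db: EHRDatabase,
    rng: np.random.Generator,
    log: RejectionLog,
    design: Optional[StudyDesign] = None,
    notes: Optional[list[str]] = None,
) -> tuple[list[MatchedSet], list[CohortMember], list[CohortMember]]:
    """Greedy seeded matching pass.

    Returns ``(matched_sets, kept_exposed, matched_controls)``. Unselected
    pool members are logged as stage-4 rejections so the global conservation
    identity holds; exposed patients with no eligible control are kept with
    an empty control list under the default keep_unmatched policy, or
    rejected under drop_unmatched.
    """
    exposed_order = sorted(exposed_list, key=lambda m: m.patient_id)
    pool_order = sorted(pool, key=lambda m: m.patient_id)
    exposed_shuffled = [exposed_order[i] for i in rng.permutation(len(exposed_order))]
    pool_shuffled = [pool_order[i] for i in rng.permutation(len(pool_order))]

    pix = _build_pool_index(pool_shuffled, db)
    matched_sets: list[MatchedSet] = []
    kept_exposed: list[CohortMember] = []
    matched_controls: list[CohortMember] = []
    pos = {id(m): i for i, m in enumerate(pool_shuffled)}
    group_id = 0
    for exposed in exposed_shuffled:
        eligible = eligible_controls(exposed, pool_shuffled, criteria, db,
                                     design=design, _index=pix)
        group_id += 1
        n_take = min(criteria.n_controls_per_exposed, len(eligible))
        if n_take == 0:
            if criteria.unmatched_policy == "drop_unmatched":
                log.record("stage4", R_NO_ELIGIBLE, exposed.patient_id)
                group_id -= 1
                continue
            if notes is not None:
                notes.append(f"{R_NO_ELIGIBLE}: exposed {exposed.patient_id} kept unmatched")
            exposed.group_id = group_id
            kept_exposed.append(exposed)
            matched_sets.append(MatchedSet(group_id, exposed.patient_id, (), exposed.index_date))
            continue
        chosen_idx = rng.choice(len(eligible), size=n_take, replace=False)
        chosen = [eligible[i] for i in sorted(chosen_idx)]
        control_ids = []
        for order, control in enumerate(chosen, start=1):
            pix.available[pos[id(control)]] = False
            control.role = ROLE_MATCHED_CONTROL
            control.index_date = exposed.index_date
            control.group_id = group_id
            control.match_order = order
            matched_controls.append(control)
            control_ids.append(control.patient_id)
        exposed.group_id = group_id
        kept_exposed.append(exposed)
        matched_sets.append(
            MatchedSet(group_id, exposed.patient_id, tuple(control_ids), exposed.index_date))

    for i, m in enumerate(pool_shuffled):
        if pix.available[i]:
            log.record("stage4", R_NOT_SELECTED, m.patient_id)
    return matched_sets, kept_exposed, matched_controls
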