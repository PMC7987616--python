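"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is deliberately naive and written straight from the study
rules: exhaustive enumeration for the logic evaluators, plain per-patient
loops for windows, rates and matching criteria. None of it shares code with
the evaluation paths it checks.
"""
from __future__ import annotations

import datetime as dt
from itertools import combinations

from ehrcohort.logic import And, EntityRef, Node, Or


# ---------------------------------------------------------------------------
# Logic oracles
# ---------------------------------------------------------------------------

def names_in(node: Node) -> set[str]:
    if isinstance(node, EntityRef):
        return {node.name}
    return names_in(node.left) | names_in(node.right)


def _satisfied(node: Node, present: set[str]) -> bool:
    if isinstance(node, EntityRef):
        return node.name in present
    if isinstance(node, And):
        return _satisfied(node.left, present) and _satisfied(node.right, present)
    return _satisfied(node.left, present) or _satisfied(node.right, present)


def loose_oracle(node: Node, dates: dict) -> dt.date | None:
    """Earliest completion date over all satisfying subsets of the present
    entities (completion of a subset = the latest date in it)."""
    present = [n for n in names_in(node) if dates.get(n) is not None]
    best = None
    for r in range(len(present) + 1):
        for subset in combinations(present, r):
            if _satisfied(node, set(subset)):
                when = max((dates[n] for n in subset), default=None)
                if when is not None and (best is None or when < best):
                    best = when
    return best


def _resolutions(node: Node):
    """All pure-And trees obtainable by resolving every Or to one child."""
    if isinstance(node, EntityRef):
        yield node
    elif isinstance(node, And):
        for lt in _resolutions(node.left):
            for rt in _resolutions(node.right):
                yield And(lt, rt)
    else:
        yield from _resolutions(node.left)
        yield from _resolutions(node.right)


def _and_tree_eval(node: Node, dates: dict):
    """(complete, in_order, completion_date) for a pure-And tree."""
    if isinstance(node, EntityRef):
        d = dates.get(node.name)
        return (d is not None, True, d)
    lc, lo, ld = _and_tree_eval(node.left, dates)
    rc, ro, rd = _and_tree_eval(node.right, dates)
    complete = lc and rc
    if not complete:
        return (False, False, None)
    in_order = lo and ro and ld <= rd
    return (True, in_order, max(ld, rd))


def strict_oracle(node: Node, dates: dict):
    """("date", d) | ("reject_order", None) | ("unsatisfied", None) by
    exhaustively enumerating Or-resolutions."""
    in_order_dates = []
    any_complete = False
    for tree in _resolutions(node):
        complete, ordered, when = _and_tree_eval(tree, dates)
        if complete:
            any_complete = True
            if ordered:
                in_order_dates.append(when)
    if in_order_dates:
        return ("date", min(in_order_dates))
    if any_complete:
        return ("reject_order", None)
    return ("unsatisfied", None)


def all_trees(n_leaves: int, labels: tuple[str, ...]):
    """Every expression tree with exactly ``n_leaves`` leaves drawn (with
    repetition) from ``labels``."""
    if n_leaves == 1:
        for lab in labels:
            yield EntityRef(lab)
        return
    for k in range(1, n_leaves):
        for left in all_trees(k, labels):
            for right in all_trees(n_leaves - k, labels):
                yield And(left, right)
                yield Or(left, right)


def all_assignments(names: list[str], dates: list[dt.date]):
    """Every map name -> date-or-None over the given date values."""
    options = [None] + list(dates)
    def rec(i):
        if i == len(names):
            yield {}
            return
        for rest in rec(i + 1):
            for opt in options:
                yield {names[i]: opt, **rest}
    yield from rec(0)


# ---------------------------------------------------------------------------
# Matching verifier (independent re-check of every criterion)
# ---------------------------------------------------------------------------

def age_on(birth: dt.date, on: dt.date) -> int:
    years = on.year - birth.year
    if (on.month, on.day) < (birth.month, birth.day):
        years -= 1
    return years


def _events_le(db, pid, codes, cutoff):
    return [e for e in db.events_of(pid) if e.code in codes and e.event_date <= cutoff]


def verify_pair(db, design, criteria, exposed_m, control_m) -> list[str]:
    """Re-check all matching criteria for one (exposed, control) pair;
    returns a list of violated criterion names (empty = pass)."""
    bad = []
    idx = exposed_m.index_date
    exp = db.patients[exposed_m.patient_id]
    ctl = db.patients[control_m.patient_id]

    if criteria.sex_match == "yes" and exp.sex != ctl.sex:
        bad.append("sex")
    if criteria.sex_match == "opposite" and exp.sex == ctl.sex:
        bad.append("sex")
    w = control_m.window
    if not (w.patient_start <= idx <= w.patient_end):
        bad.append("window")
    if abs(age_on(ctl.birth_date, idx) - age_on(exp.birth_date, idx)) > criteria.age_tolerance_years:
        bad.append("age")
    if criteria.match_townsend and exp.townsend_quintile != ctl.townsend_quintile:
        bad.append("townsend")
    if criteria.match_ethnicity and exp.ethnicity != ctl.ethnicity:
        bad.append("ethnicity")
    if criteria.registration_tolerance_days is not None:
        if abs((exp.registration_date - ctl.registration_date).days) > criteria.registration_tolerance_days:
            bad.append("registration")
    if criteria.exposure_duration is not None:
        codes = design.entity(criteria.exposure_duration.entity).definition
        fe = _events_le(db, exp.patient_id, codes, idx)
        fc = _events_le(db, ctl.patient_id, codes, idx)
        if not fe or not fc:
            bad.append("duration")
        else:
            de = (idx - min(e.event_date for e in fe)).days
            dc = (idx - min(e.event_date for e in fc)).days
            if abs(de - dc) > criteria.exposure_duration.tolerance_days:
                bad.append("duration")
    for label, names in (("treatment", criteria.baseline_treatments),
                         ("condition", criteria.baseline_conditions)):
        for name in names:
            codes = design.entity(name).definition
            if bool(_events_le(db, exp.patient_id, codes, idx)) != bool(
                    _events_le(db, ctl.patient_id, codes, idx)):
                bad.append(label)
    for mm in criteria.measurement_matches:
        codes = design.entity(mm.entity).definition
        lo = idx - dt.timedelta(days=mm.lookback_days)
        def latest(pid):
            evs = [e for e in db.events_of(pid)
                   if e.code in codes and lo <= e.event_date <= idx and e.value is not None]
            return evs[-1] if evs else None
        ev_e = latest(exp.patient_id)
        if ev_e is None:
            continue
        ev_c = latest(ctl.patient_id)
        if ev_c is None or abs(ev_c.value - ev_e.value) > mm.value_tolerance:
            bad.append("measurement")
    for name in criteria.exclude_outcomes_before_index + criteria.exclude_events_before_index:
        codes = design.entity(name).definition
        if _events_le(db, ctl.patient_id, codes, idx):
            bad.append("pre_index_exclusion")
    return bad


# ---------------------------------------------------------------------------
# Naive epidemiology loops
# ---------------------------------------------------------------------------

def naive_incidence(rows) -> tuple[int, float]:
    """(events, person_years) from (event_flag, time_days) pairs."""
    events = sum(1 for flag, _ in rows if flag)
    py = sum(t for _, t in rows) / 365.25
    return events, py


def naive_prevalence(rows, ref) -> tuple[int, int]:
    """rows of (start, end, exposed, index); returns (cases, population)."""
    pop = cases = 0
    for start, end, exposed, index in rows:
        if start <= ref <= end:
            pop += 1
            if exposed and index is not None and index <= ref:
                cases += 1
    return cases, pop
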