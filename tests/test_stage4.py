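import datetime as dt
from collections import Counter

import numpy as np

from ehrcohort import RejectionLog, StudyDesign, eligible_controls, run_stage4
from ehrcohort.design import MatchCriteria
from ehrcohort.model import EHRDatabase, PatientRecord, Practice
from ehrcohort.stage1 import CohortMember, ObservationWindow, ROLE_EXPOSED
from oracles import verify_pair

WINDOW = ObservationWindow(dt.date(2000, 1, 1), dt.date(2018, 1, 1),
                           dt.date(2000, 1, 1), dt.date(2018, 1, 1))


def _db(patients):
    prac = {"p": Practice("p", dt.date(1998, 1, 1), dt.date(2019, 1, 1))}
    return EHRDatabase(prac, {r.patient_id: r for r in patients}, [])


def _patient(pid, sex, birth_year):
    return PatientRecord(pid, "p", sex, dt.date(birth_year, 6, 1), "day",
                         dt.date(2000, 1, 1))


def _member(pid, role="potential_control", index=None):
    m = CohortMember(pid, "p", WINDOW, role=role)
    m.index_date = index
    return m


class TestEligibleControls:
    def test_age_and_sex_tolerances(self):
        # exposed F aged 50 at index; pool F49, F52, M50; age +-1, same sex
        index = dt.date(2010, 7, 1)
        db = _db([_patient("exp", "female", 1960), _patient("F49", "female", 1961),
                  _patient("F52", "female", 1958), _patient("M50", "male", 1960)])
        exposed = _member("exp", ROLE_EXPOSED, index)
        pool = [_member(p) for p in ("F49", "F52", "M50")]
        crit = MatchCriteria(n_controls_per_exposed=4, age_tolerance_years=1, sex_match="yes")
        got = eligible_controls(exposed, pool, crit, db)
        assert [m.patient_id for m in got] == ["F49"]

    def test_window_must_cover_index(self):
        db = _db([_patient("exp", "male", 1960), _patient("c1", "male", 1960)])
        exposed = _member("exp", ROLE_EXPOSED, dt.date(2010, 1, 1))
        short = CohortMember("c1", "p", ObservationWindow(
            dt.date(2000, 1, 1), dt.date(2009, 12, 31),
            dt.date(2000, 1, 1), dt.date(2018, 1, 1)))
        crit = MatchCriteria(n_controls_per_exposed=1, age_tolerance_years=99, sex_match="any")
        assert eligible_controls(exposed, [short], crit, db) == []

    def test_empty_pool(self):
        db = _db([_patient("exp", "male", 1960)])
        exposed = _member("exp", ROLE_EXPOSED, dt.date(2010, 1, 1))
        crit = MatchCriteria(n_controls_per_exposed=1)
        assert eligible_controls(exposed, [], crit, db) == []

    def test_opposite_sex_matching(self):
        db = _db([_patient("exp", "female", 1960), _patient("m", "male", 1960),
                  _patient("f", "female", 1960)])
        exposed = _member("exp", ROLE_EXPOSED, dt.date(2010, 7, 1))
        crit = MatchCriteria(n_controls_per_exposed=1, age_tolerance_years=5,
                             sex_match="opposite")
        got = eligible_controls(exposed, [_member("m"), _member("f")], crit, db)
        assert [m.patient_id for m in got] == ["m"]

    def test_townsend_missing_matches_missing(self):
        rec = [_patient("exp", "male", 1960), _patient("c1", "male", 1960),
               _patient("c2", "male", 1960)]
        rec[2] = PatientRecord("c2", "p", "male", dt.date(1960, 6, 1), "day",
                               dt.date(2000, 1, 1), townsend_quintile=3)
        db = _db(rec)
        exposed = _member("exp", ROLE_EXPOSED, dt.date(2010, 7, 1))
        crit = MatchCriteria(n_controls_per_exposed=2, age_tolerance_years=5,
                             sex_match="yes", match_townsend=True)
        got = eligible_controls(exposed, [_member("c1"), _member("c2")], crit, db)
        assert [m.patient_id for m in got] == ["c1"]  # both exposed and c1 missing


class TestRunStage4:
    def _symmetric_fixture(self, n_candidates=4):
        pats = [_patient("e1", "male", 1960), _patient("e2", "male", 1960)]
        pats += [_patient(f"c{i}", "male", 1960) for i in range(n_candidates)]
        db = _db(pats)
        exposed = [_member("e1", ROLE_EXPOSED, dt.date(2010, 1, 1)),
                   _member("e2", ROLE_EXPOSED, dt.date(2010, 1, 1))]
        pool = [_member(f"c{i}") for i in range(n_candidates)]
        return db, exposed, pool

    def test_without_replacement_exhausts_pool(self):
        db, exposed, pool = self._symmetric_fixture(4)
        crit = MatchCriteria(n_controls_per_exposed=4, age_tolerance_years=0, sex_match="yes")
        log = RejectionLog()
        sets, kept, controls = run_stage4(exposed, pool, crit, db,
                                          np.random.default_rng(5), log)
        sizes = sorted(len(s.control_ids) for s in sets)
        assert sizes == [0, 4]
        assert len(controls) == 4
        all_ids = [cid for s in sets for cid in s.control_ids]
        assert len(all_ids) == len(set(all_ids))
        assert log.stages.get("stage4", {}).get("control not selected", 0) == 0

    def test_same_seed_identical_output(self):
        crit = MatchCriteria(n_controls_per_exposed=2, age_tolerance_years=0, sex_match="yes")
        results = []
        for _ in range(2):
            db, exposed, pool = self._symmetric_fixture(6)
            sets, *_ = run_stage4(exposed, pool, crit, db,
                                  np.random.default_rng(42), RejectionLog())
            results.append([(s.group_id, s.exposed_id, s.control_ids) for s in sets])
        assert results[0] == results[1]

    def test_drop_unmatched_policy_rejects(self):
        db, exposed, pool = self._symmetric_fixture(4)
        crit = MatchCriteria(n_controls_per_exposed=4, age_tolerance_years=0,
                             sex_match="yes", unmatched_policy="drop_unmatched")
        log = RejectionLog()
        sets, kept, controls = run_stage4(exposed, pool, crit, db,
                                          np.random.default_rng(5), log)
        assert len(kept) == 1 and len(sets) == 1
        assert log.stages["stage4"]["no eligible controls"] == 1

    def test_group_ids_consecutive_and_index_copied(self):
        db, exposed, pool = self._symmetric_fixture(6)
        crit = MatchCriteria(n_controls_per_exposed=2, age_tolerance_years=0, sex_match="yes")
        sets, kept, controls = run_stage4(exposed, pool, crit, db,
                                          np.random.default_rng(0), RejectionLog())
        assert [s.group_id for s in sets] == [1, 2]
        for c in controls:
            assert c.index_date == dt.date(2010, 1, 1)
            assert c.group_id in (1, 2)

    def test_permutation_fairness_on_symmetric_pool(self):
        # 1 exposed, 6 identical candidates, pick 2: each candidate should be
        # chosen with frequency 1/3 across seeds (binomial 99% bounds).
        crit = MatchCriteria(n_controls_per_exposed=2, age_tolerance_years=0, sex_match="yes")
        n_runs = 600
        counts = Counter()
        for seed in range(n_runs):
            db, exposed, pool = self._symmetric_fixture(6)
            sets, *_ = run_stage4(exposed[:1], pool, crit, db,
                                  np.random.default_rng(seed), RejectionLog())
            for cid in sets[0].control_ids:
                counts[cid] += 1
        p = 2 / 6
        sd = (n_runs * p * (1 - p)) ** 0.5
        for cid in (f"c{i}" for i in range(6)):
            assert abs(counts[cid] - n_runs * p) < 2.576 * sd

    def test_verifier_on_randomized_fixture(self, recovery_design_dict):
        from ehrcohort import generate, SimConfig, extract
        cfg = SimConfig(seed=77, n_practices=4, patients_per_practice=250,
                        exposure_incidence_per_year=0.03)
        db = generate(cfg)
        design = StudyDesign.model_validate(recovery_design_dict)
        res = extract(db, design, seed=77)
        members = {m.patient_id: m for m in res.state.exposed + res.state.matched_controls}
        seen = set()
        n_pairs = 0
        for s in res.state.matched_sets:
            for cid in s.control_ids:
                assert cid not in seen
                seen.add(cid)
                bad = verify_pair(db, design, design.match_criteria,
                                  members[s.exposed_id], members[cid])
                assert bad == [], f"pair ({s.exposed_id},{cid}) violates {bad}"
                n_pairs += 1
        assert n_pairs > 0
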