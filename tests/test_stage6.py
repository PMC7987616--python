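import datetime as dt

import pytest
from scipy import stats

from ehrcohort import (StudyDesign, extract, summarise_incidence,
                       summarise_prevalence, poisson_exact_ci, binomial_exact_ci)
from ehrcohort.design import BaselineSpec
from ehrcohort.stage6 import extract_baseline, dataset_columns
from oracles import naive_incidence, naive_prevalence


class TestBaselines:
    def _exposed(self, toy_db, toy_design, pid):
        res = extract(toy_db, toy_design)
        return {m.patient_id: m for m in res.state.exposed}[pid]

    def test_latest_before_index_with_lookback(self, toy_db, toy_design):
        m = self._exposed(toy_db, toy_design, "pt001")
        spec = BaselineSpec(entity="BMI", rule="latest_before_index", lookback_days=735)
        value, date = extract_baseline(m, spec, toy_db, toy_design)
        assert (value, date) == (30.2, dt.date(2007, 5, 30))

    def test_lookback_excludes_stale_record(self, toy_db, toy_design):
        # pt002's only BMI is ~1680 days before index: outside a 735-day window
        m = self._exposed(toy_db, toy_design, "pt002")
        spec = BaselineSpec(entity="BMI", rule="latest_before_index", lookback_days=735)
        assert extract_baseline(m, spec, toy_db, toy_design) == (None, None)
        no_lookback = BaselineSpec(entity="BMI", rule="latest_before_index")
        assert extract_baseline(m, no_lookback, toy_db, toy_design)[0] == 28.0

    def test_never_recorded_is_missing(self, toy_db, toy_design):
        m = self._exposed(toy_db, toy_design, "pt002")
        spec = BaselineSpec(entity="Smoking", rule="latest_before_index")
        assert extract_baseline(m, spec, toy_db, toy_design) == (None, None)

    def test_earliest_ever_and_first_after_index(self, toy_db, toy_design):
        m = self._exposed(toy_db, toy_design, "pt001")
        earliest = BaselineSpec(entity="BMI", rule="earliest_ever")
        assert extract_baseline(m, earliest, toy_db, toy_design)[1] == dt.date(2006, 1, 20)
        after = BaselineSpec(entity="IschemicHeartDisease", rule="first_after_index")
        assert extract_baseline(m, after, toy_db, toy_design)[1] == dt.date(2010, 2, 10)


class TestAssemble:
    def test_cohort_row_count_and_columns(self, toy_db, toy_design):
        res = extract(toy_db, toy_design)
        n_controls = sum(len(s.control_ids) for s in res.state.matched_sets)
        assert len(res.dataset) == len(res.state.exposed) + n_controls
        assert list(res.dataset.columns) == dataset_columns(toy_design)
        assert res.dataset["follow_up_days"].min() >= 0

    def test_cross_sectional_has_no_group_or_outcome_columns(self, toy_db, toy_design):
        data = toy_design.model_dump(mode="json")
        data.update({"design_type": "cross_sectional", "outcomes": [],
                     "pre_index_outcome_exclusion": False,
                     "controls_required": False})
        data.pop("match_criteria", None)
        design = StudyDesign.model_validate(data)
        res = extract(toy_db, design)
        cols = list(res.dataset.columns)
        assert "group_id" not in cols and "exit_date" not in cols
        assert not any(c.endswith("_event") for c in cols)
        # unexposed population rows are retained with exposed_flag 0
        assert set(res.dataset["exposed_flag"]) == {0, 1}

    def test_byte_stable_across_runs(self, toy_db, toy_design):
        from ehrcohort.stage6 import write_dataset
        a = write_dataset(extract(toy_db, toy_design).dataset, None)
        b = write_dataset(extract(toy_db, toy_design).dataset, None)
        assert a == b


class TestSummaries:
    def test_poisson_ci_closed_form(self):
        # 44 events over exactly 100,000 person-years
        low, high = poisson_exact_ci(44, 100_000)
        assert low == pytest.approx(stats.chi2.ppf(0.025, 88) / 2, rel=1e-12)
        assert high == pytest.approx(stats.chi2.ppf(0.975, 90) / 2, rel=1e-12)
        assert low < 44 < high

    def test_zero_events_have_positive_upper_bound(self):
        low, high = poisson_exact_ci(0, 500)
        assert low == 0.0 and high > 0

    def test_zero_person_years_flagged(self):
        with pytest.raises(ValueError, match="person-years"):
            poisson_exact_ci(1, 0)

    def test_binomial_ci_brackets_point(self):
        low, high = binomial_exact_ci(33, 1000)
        assert low < 0.033 < high

    def test_incidence_matches_naive_loop(self, toy_db, toy_design):
        df = extract(toy_db, toy_design).dataset
        got = summarise_incidence(df, outcome=None)
        rows = []
        for _, r in df.iterrows():
            dates = [r[f"{n}_date"] for n in toy_design.outcomes]
            flag = any(isinstance(d, str) and d == r["exit_date"] for d in dates)
            rows.append((flag, float(r["follow_up_days"])))
        events, py = naive_incidence(rows)
        assert got.loc[0, "events"] == events
        assert got.loc[0, "person_years"] == pytest.approx(py)
        assert got.loc[0, "rate_per_100k"] == pytest.approx(events / py * 1e5)

    def test_yearly_person_time_conserved(self, toy_db, toy_design):
        df = extract(toy_db, toy_design).dataset
        overall = summarise_incidence(df, outcome=None)
        yearly = summarise_incidence(df, outcome=None, by=("year",))
        assert yearly["person_years"].sum() == pytest.approx(overall.loc[0, "person_years"])
        assert yearly["events"].sum() == overall.loc[0, "events"]

    def test_prevalence_matches_naive_loop(self, toy_db, toy_design):
        data = toy_design.model_dump(mode="json")
        data.update({"design_type": "cross_sectional", "outcomes": [],
                     "pre_index_outcome_exclusion": False, "controls_required": False})
        data.pop("match_criteria", None)
        df = extract(toy_db, StudyDesign.model_validate(data)).dataset
        ref = dt.date(2010, 7, 1)
        got = summarise_prevalence(df, ref)
        rows = [(dt.date.fromisoformat(r["patient_start"]),
                 dt.date.fromisoformat(r["patient_end"]),
                 int(r["exposed_flag"]) == 1,
                 dt.date.fromisoformat(r["index_date"]) if r["index_date"] else None)
                for _, r in df.iterrows()]
        cases, pop = naive_prevalence(rows, ref)
        assert got.loc[0, "cases"] == cases
        assert got.loc[0, "population"] == pop
        assert got.loc[0, "prevalence"] == pytest.approx(cases / pop)

    def test_stratified_by_sex_partitions_population(self, toy_db, toy_design):
        df = extract(toy_db, toy_design).dataset
        by_sex = summarise_incidence(df, outcome=None, by=("sex",))
        overall = summarise_incidence(df, outcome=None)
        assert by_sex["person_years"].sum() == pytest.approx(overall.loc[0, "person_years"])
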