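"""Planted-rate recovery: simulate, extract a matched cohort, re-estimate.

Generates a ~200,000 patient-year synthetic primary-care database in which
unexposed patients develop the outcome at 44 per 100,000 person-years and
exposure multiplies the hazard by 3.0. A matched cohort extraction (four
age/sex-matched controls per exposed, shared index dates, pre-index outcome
exclusion) followed by the incidence summary should recover both planted
quantities within Monte-Carlo error — the same logic a validation study
runs against licensed data, at desk scale.
"""
import math

from ehrcohort import (SimConfig, StudyDesign, extract, generate,
                       summarise_incidence)

cfg = SimConfig(seed=1)  # defaults: 22,000 patients, ~204,000 person-years
db = generate(cfg)
print(f"database: {db.n_patients} patients, {db.n_events} coded events")

design = StudyDesign.model_validate({
    "design_type": "cohort",
    "period": {"study_start": "2000-01-01", "study_end": "2019-12-31",
               "entry_age_min": 18, "entry_age_max": 99, "exit_age_max": 105},
    "entities": [
        {"name": "Exposure", "criteria": "inclusion",
         "exposure_type": "incident_only", "definition": ["EXP001"]},
        {"name": "Outcome", "definition": ["OUT001"]},
    ],
    "exposure_logic": {"expression": "Exposure", "mode": "loose"},
    "controls_required": True,
    "match_criteria": {"n_controls_per_exposed": 4, "age_tolerance_years": 1,
                       "sex_match": "yes",
                       "exclude_outcomes_before_index": ["Outcome"]},
    "outcomes": ["Outcome"],
    "pre_index_outcome_exclusion": True,
    "seed": 1,
})
result = extract(db, design)
print(f"dataset rows: {len(result.dataset)}; attrition verdict: {result.verdict}")

inc = summarise_incidence(result.dataset, outcome="Outcome", by=("exposed",))
print("\nIncidence by group (rate per 100,000 p-y, exact Poisson 95% CI):")
print(inc.to_string(index=False))

u = inc[inc["exposed"] == 0].iloc[0]
e = inc[inc["exposed"] == 1].iloc[0]
rr = e["rate_per_100k"] / u["rate_per_100k"]
se = math.sqrt(1 / e["events"] + 1 / u["events"])
print(f"\nplanted unexposed rate 44/100,000 p-y; recovered "
      f"{u['rate_per_100k']:.1f} (CI {u['ci_low']:.1f}-{u['ci_high']:.1f})")
print(f"planted rate ratio 3.0; recovered {rr:.2f} "
      f"(Monte-Carlo 1 SE on log scale: {se:.2f})")
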