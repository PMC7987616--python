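import pytest

from ehrcohort import StudyDesign, worked_toy, worked_toy_design


@pytest.fixture(scope="session")
def toy_db():
    return worked_toy()


@pytest.fixture(scope="session")
def toy_design() -> StudyDesign:
    return StudyDesign.model_validate(worked_toy_design())


@pytest.fixture()
def recovery_design_dict():
    """Matched-cohort design for the planted-rate simulations."""
    return {
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
    }
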