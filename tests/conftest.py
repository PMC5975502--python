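import pandas as pd
import pytest

from periscreen import (CohortConfig, PipelineConfig, ScreeningStudy,
                        load_pregnancy_lexicon, load_suicide_lexicon,
                        load_term_lexicon, load_trigger_lexicon)
from periscreen.synthetic import generate_cohort


@pytest.fixture(scope="session")
def pregnancy_lexicon():
    return load_pregnancy_lexicon()


@pytest.fixture(scope="session")
def suicide_lexicon():
    return load_suicide_lexicon()


@pytest.fixture(scope="session")
def term_lexicon():
    return load_term_lexicon()


@pytest.fixture(scope="session")
def triggers():
    return load_trigger_lexicon()


@pytest.fixture(scope="session")
def small_cohort():
    """400-patient synthetic cohort shared across read-only tests."""
    cfg = CohortConfig(n_patients=400, seed=3)
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def fitted_small(small_cohort):
    cfg, (patients, facts, notes) = small_cohort
    study = ScreeningStudy(patients, facts, notes, PipelineConfig(seed=3))
    return study.fit()


@pytest.fixture(scope="session")
def cohort5000():
    """One 5000-patient cohort at the default study conditions."""
    cfg = CohortConfig(n_patients=5000, seed=101)
    return cfg, generate_cohort(cfg)


def make_patient(pid="P1", birth="1985-03-10", employee=False, true_case=False,
                 race="White"):
    return {"patient_id": pid, "birth_date": pd.Timestamp(birth),
            "race": race, "ethnicity": "Non-Hispanic", "language": "English",
            "marital_status": "Single", "insurance": "Private",
            "employee_flag": employee, "true_case": true_case,
            "vital_status": "Alive"}


def make_fact(pid="P1", date="2010-01-01", system="ICD9", code="V22.1",
              clinic="Obstetrics", inpatient="outpatient"):
    return {"patient_id": pid, "date": pd.Timestamp(date), "system": system,
            "code": code, "clinic": clinic, "inpatient_flag": inpatient}
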