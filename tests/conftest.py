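import datetime as dt

import pytest

from bcqci import GeneratorConfig, generate_cohort, default_price_table
from bcqci.indicators import PatientRecord


def make_record(**overrides) -> PatientRecord:
    """A valid mild-burn survivor; override fields as needed."""
    base = dict(
        patient_id="P1",
        qci_date=dt.date(2021, 5, 3),
        age_years=40,
        sex="male",
        etiology="scald",
        tbsa_percent=4.0,
        inhalation_injury=False,
        actual_los_days=3,
        icu_days=0,
        readmission_days=0,
        n_surgeries=1,
        complications=(),
        wound_infection=False,
        died_in_qci_period=False,
        death_due_to_primary_treatment=False,
        discharge_destination="usual_residence",
        utilization={},
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture(scope="session")
def prices():
    return default_price_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-patient synthetic cohort at the default calibration."""
    return generate_cohort(GeneratorConfig(n=400, seed=1234))


@pytest.fixture(scope="session")
def default_cohort():
    """The reference-size synthetic cohort (n=1449, default seed)."""
    return generate_cohort(GeneratorConfig())
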