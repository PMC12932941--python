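from datetime import date, datetime

import pytest

from periopscreen.simulate import SimConfig, simulate_cohort
from periopscreen.types import (
    AirwayHistory,
    CaseOutcomes,
    PatientRecord,
    SurgicalCase,
    TeamRoster,
)

SCHED = datetime(2023, 6, 15, 9, 30)


def make_patient(**overrides) -> PatientRecord:
    """A healthy adult with no qualifying facts."""
    base = dict(
        patient_id="P1",
        birth_date=date(1970, 3, 1),
        sex="female",
        gfr_latest=80.0,
        airway_history=AirwayHistory(),
    )
    base.update(overrides)
    return PatientRecord(**base)


def make_case(**overrides) -> SurgicalCase:
    """A short, low-risk elective case at an eligible site."""
    base = dict(
        case_id="C1",
        patient_id="P1",
        site="main_campus",
        scheduled_start=SCHED,
        scheduled_duration_min=90,
        service="Urology",
        procedure_name="Cystoscopy",
        staffing=TeamRoster(attending_id="A1"),
        disposition="pacu",
        outcomes=CaseOutcomes(),
    )
    base.update(overrides)
    return SurgicalCase(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """A moderate simulated cohort with default (study-condition) settings."""
    return simulate_cohort(SimConfig(n_patients=600, seed=11))
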