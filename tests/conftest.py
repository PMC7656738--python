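from __future__ import annotations

from datetime import date, timedelta

import pytest

from lotline import (
    CoverageInterval,
    DiagnosisEvent,
    DrugClaim,
    PatientRecord,
    ProcedureEvent,
    SimulationConfig,
    generate_population,
)

EPOCH = date(2010, 1, 1)


def day(n: int) -> date:
    """Calendar date n days after the test epoch (2010-01-01)."""
    return EPOCH + timedelta(days=n)


@pytest.fixture
def D():
    return day


def make_patient(
    pid: str = "P1",
    birth_year: int = 1945,
    sex: str = "male",
    index: date = EPOCH,
    coverage_start: date | None = None,
    coverage_end: date | None = None,
    claims=(),
    extra_diagnoses=(),
    procedures=(),
    death: date | None = None,
    source_kind: str = "claims",
    mm_code: str = "C90.00",
) -> PatientRecord:
    """Hand-built patient: MM diagnosis at *index*, full coverage around it."""
    coverage_start = coverage_start or index - timedelta(days=400)
    coverage_end = coverage_end or index + timedelta(days=1500)
    rec = PatientRecord(
        patient_id=pid,
        birth_year=birth_year,
        sex=sex,
        death_date=death,
        source_kind=source_kind,
        diagnosis_events=[DiagnosisEvent(index, mm_code, pid)] + list(extra_diagnoses),
        drug_claims=list(claims),
        procedure_events=list(procedures),
        coverage=[
            CoverageInterval(coverage_start, coverage_end, "medical", pid),
            CoverageInterval(coverage_start, coverage_end, "pharmacy", pid),
        ],
    )
    rec.sort_events()
    return rec


@pytest.fixture
def patient_factory():
    return make_patient


@pytest.fixture(scope="session")
def small_population():
    """300 clean synthetic patients (no violations, no prior malignancies)."""
    cfg = SimulationConfig(
        n_patients=300, seed=11, violation_fraction=0.0, prior_malignancy_rate=0.0
    )
    return generate_population(cfg)
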