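import datetime as dt

import pytest

from dmpkit import codes
from dmpkit.model import (
    ClinicalObservation,
    CodedConcept,
    ConditionEntry,
    ICD10,
    MedicationEntry,
    PatientDataSet,
    PatientRecord,
    Sex,
)
from dmpkit.registry import ANTIHYPERTENSIVE, builtin_defaults

AS_OF = dt.date(2023, 6, 1)


@pytest.fixture(scope="session")
def registry():
    return builtin_defaults()


def make_patient(
    patient_id="p1",
    birth_date=dt.date(1970, 1, 15),
    sex=Sex.female,
    fmp="fmp0001",
    conditions=(),
    medications=(),
    observations=(),
) -> PatientDataSet:
    """Small hand-built patient for rule-level tests."""
    return PatientDataSet(
        patient=PatientRecord(patient_id=patient_id, birth_date=birth_date,
                              sex=sex, assigned_fmp=fmp),
        conditions=list(conditions),
        medications=list(medications),
        observations=list(observations),
    )


def condition(code: str, onset=dt.date(2020, 1, 1), status="active"):
    return ConditionEntry(
        icd10=CodedConcept(system=ICD10, code=code),
        onset_date=onset,
        clinical_status=status,
    )


def medication(tag: str = ANTIHYPERTENSIVE, start=dt.date(2020, 2, 1),
               end=None):
    return MedicationEntry(
        code=CodedConcept(system="http://www.whocc.no/atc", code="C09"),
        therapeutic_classes=frozenset({tag}),
        period_start=start,
        period_end=end,
    )


def observation(concept, value, date, unit=None, origin="ehr_sync"):
    return ClinicalObservation(
        code=concept,
        value=value,
        unit=unit if unit is not None
        else codes.DEFAULT_UNITS.get(concept.key(), "1"),
        effective_date=date,
        origin=origin,
    )
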