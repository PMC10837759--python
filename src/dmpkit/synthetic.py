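"""Seeded synthetic primary-care cohort generator.

Emulates the longitudinal records a national EHR sync would deliver:
demographics with a middle-aged concentration, chronic-disease diagnoses
by age-banded prevalence, medication flags given diagnosis, yearly
observation histories with truncated-normal noise per disease status,
and an encounter log driven by the real eligibility engine with an
adherence probability per recall.  Everything is reproducible from the
integer seed; no real demography is claimed.
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, field_validator

from dmpkit import codes
from dmpkit.eligibility import Status, Track, next_due
from dmpkit.model import (
    ClinicalObservation,
    CodedConcept,
    ConditionEntry,
    EncounterRecord,
    EncounterType,
    ICD10,
    MedicationEntry,
    PatientDataSet,
    PatientRecord,
    Sex,
    add_months,
)
from dmpkit.population import EncounterEvent
from dmpkit.registry import (
    ANTIDIABETIC,
    ANTIHYPERTENSIVE,
    ModuleRegistry,
    builtin_defaults,
)


class AgeBandRate(BaseModel):
    age_min: int
    age_max: int
    rate: float = Field(ge=0.0, le=1.0)


class ObservationSpec(BaseModel):
    """Truncated-normal noise model for one parameter."""

    mean: float
    sd: float = Field(gt=0)
    lower: float
    upper: float


_DISEASES = {
    "hypertension": ("I10", "Essential (primary) hypertension"),
    "diabetes": ("E11", "Type 2 diabetes mellitus"),
    "obesity": ("E66", "Obesity"),
}

_MEDICATION_CLASS = {
    "hypertension": (ANTIHYPERTENSIVE, "C09", "ACE inhibitor"),
    "diabetes": (ANTIDIABETIC, "A10", "Metformin"),
}


def _default_prevalence() -> dict[str, list[AgeBandRate]]:
    return {
        "hypertension": [AgeBandRate(age_min=18, age_max=39, rate=0.05),
                         AgeBandRate(age_min=40, age_max=59, rate=0.20),
                         AgeBandRate(age_min=60, age_max=120, rate=0.40)],
        "diabetes": [AgeBandRate(age_min=18, age_max=39, rate=0.03),
                     AgeBandRate(age_min=40, age_max=59, rate=0.12),
                     AgeBandRate(age_min=60, age_max=120, rate=0.20)],
        "obesity": [AgeBandRate(age_min=18, age_max=120, rate=0.20)],
    }


def _default_observation_model() -> dict[str, dict[str, ObservationSpec]]:
    """Means/SDs per parameter, keyed ``healthy`` vs the relevant disease."""
    return {
        codes.SBP.code: {
            "healthy": ObservationSpec(mean=122, sd=12, lower=80, upper=220),
            "hypertension": ObservationSpec(mean=148, sd=15, lower=90,
                                            upper=240),
        },
        codes.DBP.code: {
            "healthy": ObservationSpec(mean=78, sd=8, lower=45, upper=130),
            "hypertension": ObservationSpec(mean=92, sd=10, lower=50,
                                            upper=140),
        },
        codes.FPG.code: {
            "healthy": ObservationSpec(mean=92, sd=10, lower=55, upper=130),
            "diabetes": ObservationSpec(mean=150, sd=35, lower=70, upper=400),
        },
        codes.HBA1C.code: {
            "healthy": ObservationSpec(mean=5.4, sd=0.4, lower=4.0, upper=6.4),
            "diabetes": ObservationSpec(mean=7.8, sd=1.2, lower=5.5,
                                        upper=14.0),
        },
        codes.BMI.code: {
            "healthy": ObservationSpec(mean=25.5, sd=3.0, lower=17, upper=32),
            "obesity": ObservationSpec(mean=34.0, sd=3.0, lower=30, upper=55),
        },
        codes.HEIGHT.code: {
            "healthy": ObservationSpec(mean=168, sd=9, lower=140, upper=205),
        },
        codes.WEIGHT.code: {
            "healthy": ObservationSpec(mean=72, sd=12, lower=40, upper=140),
            "obesity": ObservationSpec(mean=96, sd=13, lower=75, upper=200),
        },
        codes.WAIST.code: {
            "healthy": ObservationSpec(mean=92, sd=11, lower=60, upper=140),
            "obesity": ObservationSpec(mean=108, sd=10, lower=85, upper=170),
        },
        codes.EGFR.code: {
            "healthy": ObservationSpec(mean=88, sd=16, lower=15, upper=140),
        },
        codes.TOTAL_CHOLESTEROL.code: {
            "healthy": ObservationSpec(mean=5.2, sd=1.0, lower=2.2,
                                       upper=11.5),
        },
        codes.LDL.code: {
            "healthy": ObservationSpec(mean=120, sd=30, lower=40, upper=300),
        },
        codes.HDL.code: {
            "healthy": ObservationSpec(mean=50, sd=12, lower=20, upper=110),
        },
        codes.TRIGLYCERIDE.code: {
            "healthy": ObservationSpec(mean=140, sd=60, lower=40, upper=600),
        },
    }


class CohortConfig(BaseModel):
    n: int = Field(gt=0)
    seed: int = 0
    index_date: dt.date = dt.date(2023, 1, 1)
    age_mean: float = 50.0
    age_sd: float = 16.0
    age_min: int = 18
    age_max: int = 95
    female_share: float = Field(default=0.562, ge=0.0, le=1.0)
    prevalence: dict[str, list[AgeBandRate]] = Field(
        default_factory=_default_prevalence)
    medication_given_diagnosis: dict[str, float] = Field(
        default_factory=lambda: {"hypertension": 0.8, "diabetes": 0.8})
    smoking_rate: float = Field(default=0.25, ge=0.0, le=1.0)
    observation_model: dict[str, dict[str, ObservationSpec]] = Field(
        default_factory=_default_observation_model)
    history_years: int = Field(default=3, gt=0)
    adherence: float = Field(default=0.7, ge=0.0, le=1.0)
    panel_size: int = Field(default=2000, gt=0)

    @field_validator("medication_given_diagnosis")
    @classmethod
    def _probs(cls, v: dict[str, float]) -> dict[str, float]:
        for disease, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"medication probability for {disease} "
                                 f"outside [0, 1]")
        return v


def _truncated_normal(rng: np.random.Generator, spec: ObservationSpec) -> float:
    for _ in range(100):
        value = rng.normal(spec.mean, spec.sd)
        if spec.lower <= value <= spec.upper:
            return float(value)
    return float(min(max(spec.mean, spec.lower), spec.upper))


def _band_rate(bands: list[AgeBandRate], age: int) -> float:
    for band in bands:
        if band.age_min <= age <= band.age_max:
            return band.rate
    return 0.0


def generate_population(config: CohortConfig) -> list[PatientDataSet]:
    """Generate `config.n` synthetic longitudinal patient records.

    Diagnosed patients carry the matching active ICD-10 condition and,
    with the configured probability, an ongoing medication of the
    matching therapeutic class.  Each patient has `history_years` yearly
    observation rounds ending at the index date, drawn from the
    disease-conditional noise model, with correct units.  Output is a
    pure function of the config (including the seed).
    """
    rng = np.random.default_rng(config.seed)
    population: list[PatientDataSet] = []
    for i in range(config.n):
        patient_id = f"p{i:06d}"
        fmp = f"fmp{i // config.panel_size:04d}"
        age = int(round(float(np.clip(rng.normal(config.age_mean, config.age_sd),
                                      config.age_min, config.age_max))))
        # birth date chosen so the completed age at the index date is exactly
        # the drawn age
        birth_date = (add_months(config.index_date, -12 * age)
                      - dt.timedelta(days=int(rng.integers(0, 365))))
        sex = Sex.female if rng.random() < config.female_share else Sex.male
        patient = PatientRecord(patient_id=patient_id, birth_date=birth_date,
                                sex=sex, assigned_fmp=fmp)

        diseases = set()
        conditions = []
        medications = []
        for disease, bands in config.prevalence.items():
            if rng.random() < _band_rate(bands, age):
                diseases.add(disease)
                icd, display = _DISEASES[disease]
                onset = add_months(config.index_date,
                                   -int(rng.integers(12, 120)))
                conditions.append(ConditionEntry(
                    icd10=CodedConcept(system=ICD10, code=icd, display=display),
                    onset_date=onset))
                med = _MEDICATION_CLASS.get(disease)
                med_p = config.medication_given_diagnosis.get(disease, 0.0)
                if med is not None and rng.random() < med_p:
                    tag, atc, name = med
                    medications.append(MedicationEntry(
                        code=CodedConcept(system="http://www.whocc.no/atc",
                                          code=atc, display=name),
                        therapeutic_classes=frozenset({tag}),
                        period_start=onset,
                    ))

        smoker = rng.random() < config.smoking_rate
        observations = []
        for back in range(config.history_years, 0, -1):
            obs_date = add_months(config.index_date, -12 * back
                                  + int(rng.integers(0, 3)))
            for code, by_status in config.observation_model.items():
                spec = by_status["healthy"]
                for disease in diseases:
                    if disease in by_status:
                        spec = by_status[disease]
                        break
                concept = codes.by_code(code)
                observations.append(ClinicalObservation(
                    code=concept,
                    value=round(_truncated_normal(rng, spec), 1),
                    unit=codes.DEFAULT_UNITS.get(concept.key(), "1"),
                    effective_date=obs_date,
                ))
            observations.append(ClinicalObservation(
                code=codes.SMOKER,
                value=1.0 if smoker else 0.0,
                unit="1",
                effective_date=obs_date,
            ))

        population.append(PatientDataSet(
            patient=patient,
            conditions=conditions,
            medications=medications,
            observations=observations,
        ))
    return population


def generate_encounter_log(
    population: list[PatientDataSet],
    months: int,
    config: CohortConfig,
    registry: Optional[ModuleRegistry] = None,
) -> tuple[list[EncounterEvent], dict[str, dict[tuple[str, str], int]]]:
    """Simulate `months` monthly recall cycles starting at the index date.

    In each month, every patient due (or overdue) for a module's track
    enters that month's target count; with the configured adherence
    probability they attend, which appends an encounter event and records
    it on the patient's dataset so later months see the updated schedule.
    The eligibility engine itself drives attendance: a patient who is not
    eligible never produces an encounter.

    Returns the event log and the per-month target table
    ``{"YYYY-MM": {(module, track): due_count}}``.
    """
    registry = registry or builtin_defaults()
    rng = np.random.default_rng(config.seed + 1)
    events: list[EncounterEvent] = []
    targets: dict[str, dict[tuple[str, str], int]] = {}
    for step in range(months):
        month_date = add_months(config.index_date, step)
        month_key = f"{month_date.year:04d}-{month_date.month:02d}"
        month_targets: dict[tuple[str, str], int] = {}
        for dataset in population:
            for module_id, module in registry.modules.items():
                schedule = next_due(dataset, module, month_date)
                if schedule.track == Track.none:
                    continue
                if schedule.status not in (Status.due_now, Status.overdue):
                    continue
                key = (module_id, schedule.track.value)
                month_targets[key] = month_targets.get(key, 0) + 1
                if rng.random() < config.adherence:
                    encounter = EncounterRecord(
                        module_id=module_id,
                        encounter_type=EncounterType(schedule.track.value),
                        date=month_date,
                        performer=dataset.patient.assigned_fmp,
                        duration_minutes=round(
                            float(rng.uniform(0.5, 3.0)), 2),
                    )
                    dataset.encounters.append(encounter)
                    events.append(EncounterEvent(
                        patient_id=dataset.patient_id,
                        module_id=module_id,
                        track=encounter.encounter_type,
                        date=month_date,
                        performer=encounter.performer,
                    ))
        targets[month_key] = month_targets
    return events, targets
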