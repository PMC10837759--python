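"""FHIR R4-aligned patient data model.

Domain types for one citizen's longitudinal primary-care record
(demographics, coded conditions, medications, observations, encounters,
treatment goals, care plans), plain-JSON FHIR R4 bundle readers/writers,
CarePlan export, incremental record merging, and validity-aware
observation lookup.

All dates are calendar dates (day granularity): every clinical rule in
scope is expressed in days, months, or years, never in time-of-day.
Month arithmetic uses calendar months with day clamping, so
Jan 31 + 1 month = Feb 28 (or 29 in a leap year).
"""

from __future__ import annotations

import datetime as dt
import logging
from enum import Enum
from typing import Iterable, Optional

from dateutil.relativedelta import relativedelta
from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger(__name__)

# Code-system URIs.  ICD-10 and LOINC where applicable; a local URN for
# national parameter codes that have no published system in scope.
ICD10 = "http://hl7.org/fhir/sid/icd-10"
LOINC = "http://loinc.org"
LOCAL = "urn:dmp:parameter"

_ORIGIN_EXT = "urn:dmp:origin"
_CLASS_EXT = "urn:dmp:therapeutic-class"
_TRACK_EXT = "urn:dmp:encounter-type"
_MODULE_SYSTEM = "urn:dmp:module"
_SET_BY_EXT = "urn:dmp:set-by"
_KIND_EXT = "urn:dmp:activity-kind"


class BundleParseError(ValueError):
    """A bundle entry could not be mapped; carries the entry index."""

    def __init__(self, index: int, message: str):
        self.index = index
        super().__init__(f"entry {index}: {message}")


class BundleStructureError(ValueError):
    """Bundle-level structural violation (e.g. not exactly one Patient)."""


class DatasetValidationError(ValueError):
    """Dataset invariant violations; carries the full list."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


class PatientIdentityError(ValueError):
    """Two datasets refer to different patients."""


# --------------------------------------------------------------------------
# calendar helpers

def add_months(date: dt.date, months: int) -> dt.date:
    """Calendar-month addition with day clamping (Jan 31 + 1m = Feb 28/29)."""
    return date + relativedelta(months=months)


def whole_months_between(earlier: dt.date, later: dt.date) -> int:
    """Completed calendar months from `earlier` to `later` (clamped days).

    The largest k >= 0 such that earlier + k months <= later.
    """
    if later < earlier:
        raise ValueError("later date precedes earlier date")
    delta = relativedelta(later, earlier)
    return delta.years * 12 + delta.months


# --------------------------------------------------------------------------
# domain types

class Sex(str, Enum):
    female = "female"
    male = "male"


class ObservationOrigin(str, Enum):
    ehr_sync = "ehr_sync"
    encounter_entry = "encounter_entry"
    self_reported = "self_reported"


class ClinicalStatus(str, Enum):
    active = "active"
    resolved = "resolved"


class EncounterType(str, Enum):
    screening = "screening"
    monitoring = "monitoring"


class Comparator(str, Enum):
    """Goal comparators: the target is met when observed value <op> target."""

    le = "le"
    ge = "ge"
    lt = "lt"
    gt = "gt"


_COMPARATOR_FN = {
    Comparator.le: lambda v, t: v <= t,
    Comparator.ge: lambda v, t: v >= t,
    Comparator.lt: lambda v, t: v < t,
    Comparator.gt: lambda v, t: v > t,
}

_FHIR_COMPARATOR = {
    Comparator.le: "<=",
    Comparator.ge: ">=",
    Comparator.lt: "<",
    Comparator.gt: ">",
}
_FHIR_COMPARATOR_INV = {v: k for k, v in _FHIR_COMPARATOR.items()}


class ActivityKind(str, Enum):
    medication_order = "medication_order"
    lab_order = "lab_order"
    referral = "referral"
    lifestyle_recommendation = "lifestyle_recommendation"
    follow_up_appointment = "follow_up_appointment"
    education_material = "education_material"


class GoalSetBy(str, Enum):
    cds_suggested = "cds_suggested"
    physician_override = "physician_override"


class CodedConcept(BaseModel):
    """A code from a named code system (ICD-10, LOINC, or local)."""

    system: str
    code: str
    display: str = ""

    model_config = {"frozen": True}

    @field_validator("system", "code")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("system and code must be non-empty")
        return v

    def key(self) -> tuple[str, str]:
        return (self.system, self.code)


class PatientRecord(BaseModel):
    patient_id: str
    birth_date: dt.date
    sex: Sex
    assigned_fmp: str = ""


class ClinicalObservation(BaseModel):
    code: CodedConcept
    value: float
    unit: str
    effective_date: dt.date
    origin: ObservationOrigin = ObservationOrigin.ehr_sync

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError("observation value must be finite")
        return v

    def identity(self) -> tuple:
        return (*self.code.key(), self.effective_date, self.origin)


class ConditionEntry(BaseModel):
    icd10: CodedConcept
    onset_date: dt.date
    clinical_status: ClinicalStatus = ClinicalStatus.active

    @field_validator("icd10")
    @classmethod
    def _icd10_shape(cls, v: CodedConcept) -> CodedConcept:
        code = v.code
        if not (code and code[0].isalpha() and len(code) >= 2
                and code[1].isdigit()):
            raise ValueError(f"not an ICD-10 shaped code: {code!r}")
        return v

    def identity(self) -> tuple:
        return (*self.icd10.key(), self.onset_date)


class MedicationEntry(BaseModel):
    code: CodedConcept
    therapeutic_classes: frozenset[str] = frozenset()
    period_start: dt.date
    period_end: Optional[dt.date] = None

    @model_validator(mode="after")
    def _period_order(self) -> "MedicationEntry":
        if self.period_end is not None and self.period_end < self.period_start:
            raise ValueError("medication period_end precedes period_start")
        return self

    def ongoing_at(self, as_of: dt.date) -> bool:
        return self.period_start <= as_of and (
            self.period_end is None or self.period_end >= as_of
        )

    def identity(self) -> tuple:
        return (*self.code.key(), self.period_start)


class EncounterRecord(BaseModel):
    module_id: str
    encounter_type: EncounterType
    date: dt.date
    performer: str = ""
    duration_minutes: float = Field(default=0.0, ge=0)

    def identity(self) -> tuple:
        return (self.module_id, self.encounter_type, self.date, self.performer)


class GoalRecord(BaseModel):
    parameter: CodedConcept
    comparator: Comparator
    target_value: float
    unit: str
    set_date: dt.date
    set_by: GoalSetBy = GoalSetBy.cds_suggested

    @field_validator("target_value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if v != v or v in (float("inf"), float("-inf")):
            raise ValueError("goal target must be finite")
        return v

    def satisfied_by(self, value: float) -> bool:
        return _COMPARATOR_FN[self.comparator](value, self.target_value)

    def identity(self) -> tuple:
        return (*self.parameter.key(), self.set_date, self.comparator)


class CarePlanActivity(BaseModel):
    kind: ActivityKind
    payload: CodedConcept
    text: str = ""
    due_date: Optional[dt.date] = None

    @model_validator(mode="after")
    def _follow_up_dated(self) -> "CarePlanActivity":
        if self.kind == ActivityKind.follow_up_appointment and self.due_date is None:
            raise ValueError("follow_up_appointment activity requires a due_date")
        return self


class CarePlanRecord(BaseModel):
    patient_id: str
    encounter_ref: str
    goals: list[GoalRecord] = Field(default_factory=list)
    activities: list[CarePlanActivity] = Field(default_factory=list)

    def identity(self) -> tuple:
        return (self.encounter_ref,)


class PatientDataSet(BaseModel):
    """One citizen's longitudinal record, the unit every engine consumes."""

    patient: PatientRecord
    conditions: list[ConditionEntry] = Field(default_factory=list)
    medications: list[MedicationEntry] = Field(default_factory=list)
    observations: list[ClinicalObservation] = Field(default_factory=list)
    encounters: list[EncounterRecord] = Field(default_factory=list)
    goals: list[GoalRecord] = Field(default_factory=list)
    care_plans: list[CarePlanRecord] = Field(default_factory=list)
    skipped_resources: int = Field(default=0, exclude=True)

    @property
    def patient_id(self) -> str:
        return self.patient.patient_id

    def active_conditions(self, as_of: Optional[dt.date] = None) -> list[ConditionEntry]:
        out = [c for c in self.conditions if c.clinical_status == ClinicalStatus.active]
        if as_of is not None:
            out = [c for c in out if c.onset_date <= as_of]
        return out

    def has_condition_prefix(self, prefix: str, as_of: Optional[dt.date] = None) -> bool:
        return any(c.icd10.code.startswith(prefix) for c in self.active_conditions(as_of))

    def on_medication_class(self, tag: str, as_of: dt.date) -> bool:
        return any(tag in m.therapeutic_classes and m.ongoing_at(as_of)
                   for m in self.medications)

    def validate_invariants(self) -> list[str]:
        problems: list[str] = []
        for obs in self.observations:
            if not obs.unit:
                problems.append(
                    f"observation {obs.code.code}@{obs.effective_date} missing unit")
        for cp in self.care_plans:
            if cp.patient_id != self.patient_id:
                problems.append(
                    f"care plan {cp.encounter_ref} references foreign patient "
                    f"{cp.patient_id}")
        return problems


class Freshness(str, Enum):
    fresh = "fresh"
    expired = "expired"
    absent = "absent"


class ObservationLookup(BaseModel):
    observation: Optional[ClinicalObservation] = None
    freshness: Freshness = Freshness.absent


def latest_observation(
    dataset: PatientDataSet,
    code: CodedConcept,
    as_of: dt.date,
    validity_months: Optional[int] = None,
) -> ObservationLookup:
    """Most recent observation of `code` dated on or before `as_of`.

    Freshness is `expired` when the observation's age in completed calendar
    months exceeds `validity_months` (an observation exactly at the validity
    boundary is still fresh), `absent` when no dated-on-or-before
    observation exists, and `fresh` otherwise.  When several observations
    share the latest date, the one entered in an encounter wins over a
    synced or self-reported one (physician-entered values are
    authoritative for prefill).
    """
    candidates = [o for o in dataset.observations
                  if o.code.key() == code.key() and o.effective_date <= as_of]
    if not candidates:
        return ObservationLookup(freshness=Freshness.absent)
    priority = {ObservationOrigin.encounter_entry: 0,
                ObservationOrigin.ehr_sync: 1,
                ObservationOrigin.self_reported: 2}
    best = max(candidates, key=lambda o: (o.effective_date, -priority[o.origin]))
    freshness = Freshness.fresh
    if validity_months is not None:
        age = whole_months_between(best.effective_date, as_of)
        if age > validity_months:
            freshness = Freshness.expired
    return ObservationLookup(observation=best, freshness=freshness)


# --------------------------------------------------------------------------
# incremental merge

def _merge_collection(base: list, delta: list) -> list:
    """Union by record identity; on collision the delta (newer) version wins.

    Output order: base order with collisions replaced in place, then new
    delta records in their own order — deterministic and idempotent.
    """
    delta_by_id = {item.identity(): item for item in delta}
    merged = []
    seen = set()
    for item in base:
        ident = item.identity()
        merged.append(delta_by_id.get(ident, item))
        seen.add(ident)
    for item in delta:
        if item.identity() not in seen:
            merged.append(item)
            seen.add(item.identity())
    return merged


def merge_incremental(base: PatientDataSet, delta: PatientDataSet) -> PatientDataSet:
    """Merge an incremental sync delta into a base record.

    Record identity is per-type (observations: code system+code,
    effective date, origin); duplicates keep the delta's version.
    Idempotent: merge(x, x) == x and merge(merge(x, d), d) == merge(x, d).
    """
    if base.patient_id != delta.patient_id:
        raise PatientIdentityError(
            f"cannot merge records of {base.patient_id!r} and {delta.patient_id!r}")
    return PatientDataSet(
        patient=delta.patient,
        conditions=_merge_collection(base.conditions, delta.conditions),
        medications=_merge_collection(base.medications, delta.medications),
        observations=_merge_collection(base.observations, delta.observations),
        encounters=_merge_collection(base.encounters, delta.encounters),
        goals=_merge_collection(base.goals, delta.goals),
        care_plans=_merge_collection(base.care_plans, delta.care_plans),
    )


# --------------------------------------------------------------------------
# FHIR R4 JSON mapping

def _coding_to_concept(codeable: dict) -> CodedConcept:
    coding = (codeable or {}).get("coding") or []
    if not coding:
        raise ValueError("CodeableConcept without coding")
    c = coding[0]
    return CodedConcept(system=c.get("system", LOCAL), code=c["code"],
                        display=c.get("display", ""))


def _concept_to_codeable(concept: CodedConcept) -> dict:
    coding = {"system": concept.system, "code": concept.code}
    if concept.display:
        coding["display"] = concept.display
    return {"coding": [coding]}


def _ext(resource: dict, url: str) -> list:
    return [e for e in resource.get("extension", []) if e.get("url") == url]


def _date(value: str) -> dt.date:
    return dt.date.fromisoformat(value[:10])


def _patient_from_fhir(res: dict) -> PatientRecord:
    gp = res.get("generalPractitioner") or [{}]
    fmp = gp[0].get("identifier", {}).get("value", "")
    return PatientRecord(
        patient_id=res["id"],
        birth_date=_date(res["birthDate"]),
        sex=Sex(res["gender"]),
        assigned_fmp=fmp,
    )


def _patient_to_fhir(p: PatientRecord) -> dict:
    res = {
        "resourceType": "Patient",
        "id": p.patient_id,
        "gender": p.sex.value,
        "birthDate": p.birth_date.isoformat(),
    }
    if p.assigned_fmp:
        res["generalPractitioner"] = [{"identifier": {"value": p.assigned_fmp}}]
    return res


def _condition_from_fhir(res: dict) -> ConditionEntry:
    status_coding = (res.get("clinicalStatus", {}).get("coding") or [{}])[0]
    return ConditionEntry(
        icd10=_coding_to_concept(res["code"]),
        onset_date=_date(res["onsetDateTime"]),
        clinical_status=ClinicalStatus(status_coding.get("code", "active")),
    )


def _condition_to_fhir(c: ConditionEntry, patient_id: str) -> dict:
    return {
        "resourceType": "Condition",
        "subject": {"reference": f"Patient/{patient_id}"},
        "code": _concept_to_codeable(c.icd10),
        "onsetDateTime": c.onset_date.isoformat(),
        "clinicalStatus": {
            "coding": [{
                "system": "http://terminology.hl7.org/CodeSystem/condition-clinical",
                "code": c.clinical_status.value,
            }]
        },
    }


def _observation_from_fhir(res: dict) -> ClinicalObservation:
    vq = res["valueQuantity"]
    origin_ext = _ext(res, _ORIGIN_EXT)
    origin = ObservationOrigin(origin_ext[0]["valueCode"]) if origin_ext \
        else ObservationOrigin.ehr_sync
    return ClinicalObservation(
        code=_coding_to_concept(res["code"]),
        value=float(vq["value"]),
        unit=vq.get("unit", ""),
        effective_date=_date(res["effectiveDateTime"]),
        origin=origin,
    )


def _observation_to_fhir(o: ClinicalObservation, patient_id: str) -> dict:
    return {
        "resourceType": "Observation",
        "status": "final",
        "subject": {"reference": f"Patient/{patient_id}"},
        "code": _concept_to_codeable(o.code),
        "valueQuantity": {"value": o.value, "unit": o.unit},
        "effectiveDateTime": o.effective_date.isoformat(),
        "extension": [{"url": _ORIGIN_EXT, "valueCode": o.origin.value}],
    }


def _medication_from_fhir(res: dict) -> MedicationEntry:
    period = res.get("effectivePeriod", {})
    classes = frozenset(e["valueCode"] for e in _ext(res, _CLASS_EXT))
    end = period.get("end")
    return MedicationEntry(
        code=_coding_to_concept(res["medicationCodeableConcept"]),
        therapeutic_classes=classes,
        period_start=_date(period["start"]),
        period_end=_date(end) if end else None,
    )


def _medication_to_fhir(m: MedicationEntry, patient_id: str) -> dict:
    period = {"start": m.period_start.isoformat()}
    if m.period_end is not None:
        period["end"] = m.period_end.isoformat()
    return {
        "resourceType": "MedicationStatement",
        "status": "active" if m.period_end is None else "completed",
        "subject": {"reference": f"Patient/{patient_id}"},
        "medicationCodeableConcept": _concept_to_codeable(m.code),
        "effectivePeriod": period,
        "extension": [{"url": _CLASS_EXT, "valueCode": tag}
                      for tag in sorted(m.therapeutic_classes)],
    }


def _encounter_from_fhir(res: dict) -> EncounterRecord:
    type_coding = (res.get("type") or [{}])[0].get("coding", [{}])[0]
    track_ext = _ext(res, _TRACK_EXT)
    track = EncounterType(track_ext[0]["valueCode"]) if track_ext \
        else EncounterType.screening
    performer = ""
    for part in res.get("participant", []):
        performer = part.get("individual", {}).get("identifier", {}).get("value", "")
        if performer:
            break
    length = res.get("length", {})
    return EncounterRecord(
        module_id=type_coding["code"],
        encounter_type=track,
        date=_date(res["period"]["start"]),
        performer=performer,
        duration_minutes=float(length.get("value", 0.0)),
    )


def _encounter_to_fhir(e: EncounterRecord, patient_id: str) -> dict:
    res = {
        "resourceType": "Encounter",
        "status": "finished",
        "class": {"system": "http://terminology.hl7.org/CodeSystem/v3-ActCode",
                  "code": "AMB"},
        "subject": {"reference": f"Patient/{patient_id}"},
        "type": [{"coding": [{"system": _MODULE_SYSTEM, "code": e.module_id}]}],
        "period": {"start": e.date.isoformat()},
        "length": {"value": e.duration_minutes, "unit": "min"},
        "extension": [{"url": _TRACK_EXT, "valueCode": e.encounter_type.value}],
    }
    if e.performer:
        res["participant"] = [{"individual": {"identifier": {"value": e.performer}}}]
    return res


def _goal_from_fhir(res: dict) -> GoalRecord:
    target = res["target"][0]
    dq = target["detailQuantity"]
    set_by_ext = _ext(res, _SET_BY_EXT)
    set_by = GoalSetBy(set_by_ext[0]["valueCode"]) if set_by_ext \
        else GoalSetBy.cds_suggested
    return GoalRecord(
        parameter=_coding_to_concept(target["measure"]),
        comparator=_FHIR_COMPARATOR_INV[dq["comparator"]],
        target_value=float(dq["value"]),
        unit=dq.get("unit", ""),
        set_date=_date(res["startDate"]),
        set_by=set_by,
    )


def _goal_to_fhir(g: GoalRecord, patient_id: str) -> dict:
    return {
        "resourceType": "Goal",
        "lifecycleStatus": "active",
        "subject": {"reference": f"Patient/{patient_id}"},
        "description": {"text": g.parameter.display or g.parameter.code},
        "startDate": g.set_date.isoformat(),
        "target": [{
            "measure": _concept_to_codeable(g.parameter),
            "detailQuantity": {
                "value": g.target_value,
                "unit": g.unit,
                "comparator": _FHIR_COMPARATOR[g.comparator],
            },
        }],
        "extension": [{"url": _SET_BY_EXT, "valueCode": g.set_by.value}],
    }


def _activity_to_fhir(a: CarePlanActivity) -> dict:
    detail = {
        "status": "not-started",
        "code": _concept_to_codeable(a.payload),
        "extension": [{"url": _KIND_EXT, "valueCode": a.kind.value}],
    }
    if a.text:
        detail["description"] = a.text
    if a.due_date is not None:
        detail["scheduledPeriod"] = {"end": a.due_date.isoformat()}
    return {"detail": detail}


def _activity_from_fhir(activity: dict) -> CarePlanActivity:
    detail = activity["detail"]
    kind_ext = _ext(detail, _KIND_EXT)
    if not kind_ext:
        raise ValueError("care plan activity lacks a kind")
    end = detail.get("scheduledPeriod", {}).get("end")
    return CarePlanActivity(
        kind=ActivityKind(kind_ext[0]["valueCode"]),
        payload=_coding_to_concept(detail["code"]),
        text=detail.get("description", ""),
        due_date=_date(end) if end else None,
    )


def export_care_plan(plan: CarePlanRecord) -> dict:
    """Serialize a care plan as a standalone FHIR R4 CarePlan document.

    Goals are carried as contained Goal resources referenced from
    ``CarePlan.goal``; activities map to ``activity.detail`` entries with
    the domain activity kind in an extension.
    """
    contained = []
    goal_refs = []
    for i, g in enumerate(plan.goals):
        res = _goal_to_fhir(g, plan.patient_id)
        res["id"] = f"goal-{i}"
        contained.append(res)
        goal_refs.append({"reference": f"#goal-{i}"})
    doc = {
        "resourceType": "CarePlan",
        "status": "active",
        "intent": "plan",
        "subject": {"reference": f"Patient/{plan.patient_id}"},
        "encounter": {"reference": f"Encounter/{plan.encounter_ref}"},
        "activity": [_activity_to_fhir(a) for a in plan.activities],
    }
    if contained:
        doc["contained"] = contained
        doc["goal"] = goal_refs
    return doc


def care_plan_from_fhir(doc: dict, patient_id: Optional[str] = None) -> CarePlanRecord:
    """Inverse of :func:`export_care_plan`."""
    pid = patient_id or doc["subject"]["reference"].split("/", 1)[1]
    encounter_ref = doc.get("encounter", {}).get("reference", "").split("/")[-1]
    goals = [_goal_from_fhir(res) for res in doc.get("contained", [])
             if res.get("resourceType") == "Goal"]
    activities = [_activity_from_fhir(a) for a in doc.get("activity", [])]
    return CarePlanRecord(patient_id=pid, encounter_ref=encounter_ref,
                          goals=goals, activities=activities)


_SUPPORTED = {"Patient", "Condition", "Observation", "MedicationStatement",
              "Encounter", "Goal", "CarePlan"}


def read_bundle(document: dict) -> PatientDataSet:
    """Map a FHIR R4 Bundle onto a :class:`PatientDataSet`.

    The bundle must contain exactly one Patient.  Unsupported resource
    types are skipped; the skip count is logged and recorded on
    ``dataset.skipped_resources``.  A malformed entry raises
    :class:`BundleParseError` naming the entry index.
    """
    if document.get("resourceType") != "Bundle":
        raise BundleStructureError("document is not a FHIR Bundle")
    entries = document.get("entry", [])
    patients: list[PatientRecord] = []
    conditions, medications, observations = [], [], []
    encounters, goals, care_plans = [], [], []
    skipped = 0
    for i, entry in enumerate(entries):
        res = entry.get("resource", {})
        rtype = res.get("resourceType")
        try:
            if rtype == "Patient":
                patients.append(_patient_from_fhir(res))
            elif rtype == "Condition":
                conditions.append(_condition_from_fhir(res))
            elif rtype == "Observation":
                observations.append(_observation_from_fhir(res))
            elif rtype == "MedicationStatement":
                medications.append(_medication_from_fhir(res))
            elif rtype == "Encounter":
                encounters.append(_encounter_from_fhir(res))
            elif rtype == "Goal":
                goals.append(_goal_from_fhir(res))
            elif rtype == "CarePlan":
                care_plans.append(res)  # needs patient_id; resolved below
            else:
                skipped += 1
        except BundleStructureError:
            raise
        except Exception as exc:
            raise BundleParseError(i, f"{rtype}: {exc}") from exc
    if len(patients) != 1:
        raise BundleStructureError(
            f"bundle must contain exactly one Patient, found {len(patients)}")
    patient = patients[0]
    plans = [care_plan_from_fhir(doc, patient.patient_id) for doc in care_plans]
    if skipped:
        logger.warning("read_bundle skipped %d unsupported resource(s)", skipped)
    return PatientDataSet(
        patient=patient,
        conditions=conditions,
        medications=medications,
        observations=observations,
        encounters=encounters,
        goals=goals,
        care_plans=plans,
        skipped_resources=skipped,
    )


def write_bundle(dataset: PatientDataSet) -> dict:
    """Serialize a dataset as a FHIR R4 collection Bundle.

    Raises :class:`DatasetValidationError` listing every invariant
    violation rather than stopping at the first.
    """
    problems = dataset.validate_invariants()
    if problems:
        raise DatasetValidationError(problems)
    pid = dataset.patient_id
    resources: list[dict] = [_patient_to_fhir(dataset.patient)]
    resources += [_condition_to_fhir(c, pid) for c in dataset.conditions]
    resources += [_observation_to_fhir(o, pid) for o in dataset.observations]
    resources += [_medication_to_fhir(m, pid) for m in dataset.medications]
    resources += [_encounter_to_fhir(e, pid) for e in dataset.encounters]
    resources += [_goal_to_fhir(g, pid) for g in dataset.goals]
    resources += [export_care_plan(p) for p in dataset.care_plans]
    return {
        "resourceType": "Bundle",
        "type": "collection",
        "entry": [{"resource": r} for r in resources],
    }
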