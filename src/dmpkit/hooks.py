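"""CDS Hooks service layer.

Exposes each decision-support rule family behind the CDS Hooks
request/response contract: :func:`cds_discovery` lists one service per
family with its prefetch template, and :func:`invoke_service` parses the
prefetched FHIR bundle into a patient record, runs the family's library
function, and serializes the resulting cards per the CDS Hooks card
schema.  The transport is in-process; a thin HTTP wrapper for shell use
lives in :mod:`dmpkit.server`.  The service layer adds nothing to the
library layer: the full library card is embedded in each response card's
extension, byte-identical to a direct library call.
"""

from __future__ import annotations

import datetime as dt
import json
from typing import Any, Optional

from dmpkit import cds, codes
from dmpkit.cds import CardKind, CdsCard
from dmpkit.model import PatientDataSet, read_bundle
from dmpkit.registry import ModuleRegistry, builtin_defaults
from dmpkit.validation import validate_hooks_request

_SOURCE = {"label": "dmpkit disease management services"}

_PATIENT_PREFETCH = {
    "patientBundle": "Patient/{{context.patientId}}/$everything",
}

# one service per rule family
SERVICES: list[dict[str, Any]] = [
    {"id": "risk-assessment", "hook": "patient-view",
     "title": "Cardiovascular risk assessment",
     "description": "10-year fatal cardiovascular risk via the SCORE "
                    "functional form, with risk category."},
    {"id": "diagnosis-recommendation", "hook": "order-select",
     "title": "Diagnosis recommendations",
     "description": "ICD-10 coded diagnosis suggestions from the module's "
                    "diagnostic rules."},
    {"id": "lab-order-guidance", "hook": "patient-view",
     "title": "Required lab panel",
     "description": "Personalized list of lab tests that are expired or "
                    "never measured, per the module's validity periods."},
    {"id": "lab-based-referral", "hook": "patient-view",
     "title": "Lab-driven referral suggestions",
     "description": "Specialist referrals driven by lab results, e.g. "
                    "nephrology when eGFR is below 60 mL/min/1.73m2."},
    {"id": "goal-recommendation", "hook": "patient-view",
     "title": "Treatment goal suggestions",
     "description": "Risk- and comorbidity-keyed treatment goal targets "
                    "(blood pressure, lipids, glycemia, weight)."},
    {"id": "medication-advice", "hook": "order-select",
     "title": "Medication suggestions and contraindications",
     "description": "Candidate medication classes filtered against the "
                    "comorbidity-keyed contraindication table."},
    {"id": "preventive-referral", "hook": "patient-view",
     "title": "Preventive consultation referrals",
     "description": "Recurring preventive referrals, e.g. the yearly "
                    "retinopathy check during diabetes monitoring."},
    {"id": "follow-up-recommendation", "hook": "encounter-discharge",
     "title": "Follow-up scheduling",
     "description": "Recall interval and due date from the module's "
                    "interval rules, keyed by risk or control status."},
    {"id": "module-transition", "hook": "patient-view",
     "title": "Care pathway transition prompts",
     "description": "Prompts to continue into another disease module, e.g. "
                    "diabetes screening when fasting glucose exceeds "
                    "110 mg/dL."},
]


class InvalidRequestError(ValueError):
    """400-equivalent: the request violates the CDS Hooks schema."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        self.status = 400
        super().__init__("; ".join(problems))


class UnknownServiceError(KeyError):
    """404-equivalent: no such service id."""

    def __init__(self, service_id: str):
        self.status = 404
        super().__init__(f"unknown CDS service {service_id!r}")


def cds_discovery() -> dict:
    """CDS Hooks discovery document: one descriptor per rule family."""
    services = []
    for svc in SERVICES:
        entry = dict(svc)
        entry["prefetch"] = dict(_PATIENT_PREFETCH)
        services.append(entry)
    return {"services": services}


_INDICATOR = {
    CardKind.contraindication_warning: "warning",
    CardKind.module_transition_prompt: "warning",
}


def card_to_hooks(card: CdsCard) -> dict:
    """Serialize one library card per the CDS Hooks card schema.

    The full library card rides along in the extension, so the service
    layer is a faithful transport of the library layer.
    """
    summary = card.rationale if len(card.rationale) <= 140 \
        else card.rationale[:137] + "..."
    hooks_card = {
        "summary": summary,
        "detail": card.rationale,
        "indicator": _INDICATOR.get(card.kind, "info"),
        "source": dict(_SOURCE),
        "suggestions": [{
            "label": f"{card.kind.value.replace('_', ' ')} ({card.rule_id})",
        }],
        "extension": {"dmp-card": card.model_dump(mode="json")},
    }
    return hooks_card


def _data_request_card(detail: str) -> dict:
    return {
        "summary": "Patient data required",
        "detail": detail,
        "indicator": "info",
        "source": dict(_SOURCE),
        "suggestions": [{"label": "provide patient data"}],
        "extension": {"dmp-card": None},
    }


def run_service(
    service_id: str,
    dataset: PatientDataSet,
    context: dict,
    registry: ModuleRegistry,
) -> list[CdsCard]:
    """Library-layer execution of one service on a parsed patient record."""
    as_of = dt.date.fromisoformat(context.get("asOf")) if context.get("asOf") \
        else dt.date.today()
    module_id = context.get("moduleId", "hypertension")
    track = context.get("track", "screening")
    values = {str(k): float(v) for k, v in (context.get("values") or {}).items()}
    if module_id not in registry.modules:
        raise InvalidRequestError([f"unknown moduleId {module_id!r}"])
    module = registry.module(module_id)

    if service_id == "risk-assessment":
        from dmpkit.eligibility import age_at
        from dmpkit.model import latest_observation
        sbp = values.get(codes.SBP.code)
        if sbp is None:
            found = latest_observation(dataset, codes.SBP, as_of)
            sbp = found.observation.value if found.observation else None
        chol = values.get(codes.TOTAL_CHOLESTEROL.code)
        if chol is None:
            found = latest_observation(dataset, codes.TOTAL_CHOLESTEROL, as_of)
            chol = found.observation.value if found.observation else None
        smoker = values.get(codes.SMOKER.code)
        if smoker is None:
            found = latest_observation(dataset, codes.SMOKER, as_of)
            smoker = found.observation.value if found.observation else 0.0
        if sbp is None or chol is None:
            return [CdsCard(
                rule_id="score-risk", kind=CardKind.lab_order,
                code=codes.TOTAL_CHOLESTEROL if chol is None else codes.SBP,
                status="absent",
                rationale="Risk scoring needs systolic BP and total "
                          "cholesterol measurements")]
        age = min(max(age_at(dataset.patient.birth_date, as_of), 30), 90)
        result = cds.cvd_risk_score(age=age, sex=dataset.patient.sex,
                                    smoker=smoker >= 0.5, sbp=sbp,
                                    total_cholesterol=chol)
        return [cds.risk_score_card(result)]
    if service_id == "diagnosis-recommendation":
        return cds.recommend_diagnosis(values, module, dataset, as_of)
    if service_id == "lab-order-guidance":
        return cds.required_lab_panel(dataset, module, as_of)
    if service_id in ("lab-based-referral", "preventive-referral"):
        cards = cds.referral_advice(dataset, module, as_of, track)
        if service_id == "lab-based-referral":
            return [c for c in cards if c.rule_id == "egfr-nephrology"]
        return [c for c in cards if c.rule_id != "egfr-nephrology"]
    if service_id == "goal-recommendation":
        return cds.recommend_goals(dataset, module, None, as_of)
    if service_id == "medication-advice":
        candidates = list(context.get("candidateClasses") or [])
        return cds.medication_advice(dataset, module, candidates, as_of)
    if service_id == "follow-up-recommendation":
        _, card = cds.follow_up_interval(
            module, track, risk_category=context.get("riskCategory"),
            control_status=context.get("controlStatus"), as_of=as_of)
        return [card]
    if service_id == "module-transition":
        return cds.module_transition_check(values, dataset, as_of,
                                           module_id, track)
    raise UnknownServiceError(service_id)


def invoke_service(
    service_id: str,
    request: dict,
    registry: Optional[ModuleRegistry] = None,
) -> dict:
    """Run one CDS service on a CDS Hooks request document.

    Parses the prefetched patient bundle, executes the rule family, and
    returns a ``{"cards": [...]}`` response.  A schema-invalid request
    raises :class:`InvalidRequestError`; an unknown service id raises
    :class:`UnknownServiceError`.  An empty prefetch yields a
    data-request card, never a failure.
    """
    if service_id not in {svc["id"] for svc in SERVICES}:
        raise UnknownServiceError(service_id)
    problems = validate_hooks_request(request)
    if problems:
        raise InvalidRequestError(problems)
    registry = registry or builtin_defaults()
    bundle = (request.get("prefetch") or {}).get("patientBundle")
    if not bundle:
        return {"cards": [_data_request_card(
            "No patient bundle was prefetched; supply "
            "prefetch.patientBundle to evaluate this service")]}
    try:
        dataset = read_bundle(bundle)
    except Exception as exc:
        raise InvalidRequestError([f"prefetch.patientBundle: {exc}"]) from exc
    cards = run_service(service_id, dataset, request.get("context", {}),
                        registry)
    return {"cards": [card_to_hooks(c) for c in cards]}


def canonical_cards_json(cards: list[CdsCard]) -> str:
    """Deterministic serialization used to compare card lists byte-wise."""
    return json.dumps([c.model_dump(mode="json") for c in cards],
                      sort_keys=True, separators=(",", ":"))
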