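"""Care-pathway encounter execution.

An encounter walks a module's page flow as a state machine: pages are
prefilled from the freshest stored observations (with expired parameters
flagged for renewal), the physician enters or confirms values page by
page, transition predicates pick the next page (first match wins, every
page ends in a catch-all), and attached decision-support rules emit
cards as each page completes.  Completing the encounter assembles the
accepted cards into a care plan, records the encounter, and recomputes
the affected modules' schedules.
"""

from __future__ import annotations

import datetime as dt
import itertools
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field

from dmpkit import cds as cds_rules
from dmpkit import codes
from dmpkit.eligibility import ScheduleStatus, Track, evaluate_eligibility, next_due
from dmpkit.flows import (  # re-exported: part of the pathway surface
    TERMINAL,
    FlowValidationReport,
    PageDefinition,
    PageFlow,
    RequiredParameter,
    StepKind,
    Transition,
    validate_flow,
)
from dmpkit.model import (
    ActivityKind,
    CarePlanActivity,
    CarePlanRecord,
    ClinicalObservation,
    CodedConcept,
    Comparator,
    EncounterRecord,
    EncounterType,
    Freshness,
    GoalRecord,
    GoalSetBy,
    ICD10,
    ConditionEntry,
    PatientDataSet,
    latest_observation,
)
from dmpkit.predicates import EvalContext
from dmpkit.registry import DiseaseModuleDefinition, ModuleRegistry

__all__ = [
    "TERMINAL", "FlowValidationReport", "PageDefinition", "PageFlow",
    "RequiredParameter", "StepKind", "Transition", "validate_flow",
    "EncounterSession", "SessionStatus", "CompletedEncounter",
    "EligibilityError", "SessionStateError", "UnitError", "SchemaError",
    "start_encounter", "submit_page", "complete_encounter",
]

_session_counter = itertools.count(1)


class EligibilityError(ValueError):
    """Patient is not eligible for the requested module/track."""

    def __init__(self, module_id: str, track: str, reasons: list[str]):
        self.reasons = reasons
        super().__init__(
            f"patient not eligible for {module_id}/{track}: "
            + "; ".join(reasons))


class SessionStateError(RuntimeError):
    pass


class UnitError(ValueError):
    pass


class SchemaError(ValueError):
    pass


class SessionStatus(str, Enum):
    in_progress = "in_progress"
    completed = "completed"
    abandoned = "abandoned"


class PrefillEntry(BaseModel):
    code: str
    value: float
    unit: str
    origin: str
    effective_date: dt.date
    freshness: Freshness


class EncounterSession(BaseModel):
    session_id: str
    dataset: PatientDataSet          # working copy; grows during the session
    module: DiseaseModuleDefinition
    track: Track
    as_of: dt.date
    flow: PageFlow
    current_page: str
    status: SessionStatus = SessionStatus.in_progress
    entered_values: dict[str, float] = Field(default_factory=dict)
    prefill: dict[str, PrefillEntry] = Field(default_factory=dict)
    emitted_cards: list[cds_rules.CdsCard] = Field(default_factory=list)
    visited_pages: list[str] = Field(default_factory=list)
    renewal_flags: list[str] = Field(default_factory=list)

    def effective_values(self) -> dict[str, float]:
        """Session view of parameter values: prefill overlaid by anything the
        physician entered (prefill never overwrites an entered value)."""
        merged = {code: e.value for code, e in self.prefill.items()
                  if e.freshness == Freshness.fresh}
        merged.update(self.entered_values)
        return merged

    def card(self, rule_id: str) -> cds_rules.CdsCard:
        for c in self.emitted_cards:
            if c.rule_id == rule_id:
                return c
        raise KeyError(f"no card with rule_id {rule_id!r}")

    def accept_card(self, rule_id: str,
                    physician_override: bool = False) -> None:
        card = self.card(rule_id)
        card.accepted = cds_rules.Acceptance.accepted
        if physician_override and card.kind == cds_rules.CardKind.goal_suggestion:
            card.status = "physician_override"

    def reject_card(self, rule_id: str) -> None:
        self.card(rule_id).accepted = cds_rules.Acceptance.rejected


class CompletedEncounter(BaseModel):
    care_plan: CarePlanRecord
    encounter: EncounterRecord
    schedule_updates: dict[str, ScheduleStatus]
    transition_prompts: list[cds_rules.CdsCard]
    dataset: PatientDataSet


def start_encounter(
    dataset: PatientDataSet,
    module: DiseaseModuleDefinition,
    track: str,
    as_of: dt.date,
    registry: Optional[ModuleRegistry] = None,
    flow: Optional[PageFlow] = None,
) -> EncounterSession:
    """Open a session at the flow's entry page with prefilled parameters.

    Raises :class:`EligibilityError` (naming the violated atoms) when the
    patient is not on the requested track at `as_of`.  Every
    prefill-enabled parameter of the flow is populated from the freshest
    stored observation; parameters older than their validity period are
    flagged for renewal, and their stale values are not used by
    transition predicates.
    """
    track = Track(track)
    decision = evaluate_eligibility(dataset, module, as_of)
    if decision.track != track:
        raise EligibilityError(module.module_id, track.value, decision.reasons)
    if flow is None:
        if registry is None:
            from dmpkit.registry import builtin_defaults
            registry = builtin_defaults()
        flow = registry.flow(module.flow_for(track.value))
    session = EncounterSession(
        session_id=f"enc-{dataset.patient_id}-{as_of.isoformat()}-"
                   f"{next(_session_counter)}",
        dataset=dataset.model_copy(deep=True),
        module=module,
        track=track,
        as_of=as_of,
        flow=flow,
        current_page=flow.entry_page,
        visited_pages=[flow.entry_page],
    )
    for page in flow.pages:
        for rp in page.required_parameters:
            if not rp.prefill or rp.code in session.prefill:
                continue
            concept = codes.by_code(rp.code)
            validity = rp.validity_months or module.validity_periods.get(rp.code)
            found = latest_observation(dataset, concept, as_of, validity)
            if found.observation is None:
                continue
            entry = PrefillEntry(
                code=rp.code,
                value=found.observation.value,
                unit=found.observation.unit,
                origin=found.observation.origin.value,
                effective_date=found.observation.effective_date,
                freshness=found.freshness,
            )
            session.prefill[rp.code] = entry
            if found.freshness == Freshness.expired:
                session.renewal_flags.append(rp.code)
    return session


def _record_entered(session: EncounterSession, code: str, value: float) -> None:
    concept = codes.by_code(code)
    session.entered_values[code] = value
    obs = ClinicalObservation(
        code=concept,
        value=value,
        unit=codes.DEFAULT_UNITS.get(concept.key(), "1"),
        effective_date=session.as_of,
        origin="encounter_entry",
    )
    # replace any same-day encounter entry for the same code
    session.dataset.observations = [
        o for o in session.dataset.observations if o.identity() != obs.identity()
    ] + [obs]


def _run_rule(session: EncounterSession, rule_id: str) -> list[cds_rules.CdsCard]:
    module = session.module
    values = session.effective_values()
    rule = next((r for r in module.cds_rules if r.rule_id == rule_id), None)
    family = rule.family if rule is not None else rule_id
    if family == "diagnosis_suggestion":
        cards = cds_rules.recommend_diagnosis(values, module, session.dataset,
                                              session.as_of)
        return [c for c in cards if c.rule_id == rule_id]
    if family == "risk_score":
        return _run_risk_score(session, rule_id)
    if family in ("referral_suggestion", "preventive_referral"):
        cards = cds_rules.referral_advice(session.dataset, module,
                                          session.as_of, session.track.value)
        wanted = {rule_id}
        return [c for c in cards if c.rule_id in wanted]
    if family == "goal_suggestion":
        risk = _session_risk(session)
        return cds_rules.recommend_goals(session.dataset, module, risk,
                                         session.as_of)
    if family == "follow_up_suggestion":
        risk = _session_risk(session)
        _, card = cds_rules.follow_up_interval(
            module, session.track.value,
            risk_category=risk.category if risk else None,
            as_of=session.as_of)
        return [card]
    if family == "module_transition":
        return cds_rules.module_transition_check(
            values, session.dataset, session.as_of,
            module.module_id, session.track.value)
    return []


def _session_risk(session: EncounterSession) -> Optional[cds_rules.RiskResult]:
    for card in session.emitted_cards:
        if card.kind == cds_rules.CardKind.risk_score and card.value is not None:
            from dmpkit.predicates import categorize_risk
            return cds_rules.RiskResult(
                ten_year_risk_percent=card.value,
                category=card.status or categorize_risk(card.value),
                inputs_used={})
    return None


def _run_risk_score(session: EncounterSession,
                    rule_id: str) -> list[cds_rules.CdsCard]:
    from dmpkit.eligibility import age_at

    values = session.effective_values()
    sbp = values.get(codes.SBP.code)
    chol = values.get(codes.TOTAL_CHOLESTEROL.code)
    smoker = values.get(codes.SMOKER.code, 0.0)
    if sbp is None or chol is None:
        return [cds_rules.CdsCard(
            rule_id=rule_id, kind=cds_rules.CardKind.lab_order,
            code=codes.TOTAL_CHOLESTEROL if chol is None else codes.SBP,
            status="absent",
            rationale="Risk scoring needs systolic BP and total cholesterol")]
    age = age_at(session.dataset.patient.birth_date, session.as_of)
    age = min(max(age, 30), 90)
    result = cds_rules.cvd_risk_score(
        age=age, sex=session.dataset.patient.sex, smoker=smoker >= 0.5,
        sbp=sbp, total_cholesterol=chol)
    _record_entered(session, codes.CVD_RISK.code, result.ten_year_risk_percent)
    return [cds_rules.risk_score_card(result, rule_id)]


def submit_page(
    session: EncounterSession,
    values: Optional[dict[str, float]] = None,
    deferred: Optional[set[str]] = None,
) -> tuple[str, list[cds_rules.CdsCard]]:
    """Record the page's values, run its attached rules, and transition.

    `values` maps parameter code to value (floats in the parameter's
    default unit) or to a ``(value, unit)`` pair; a wrong unit raises
    :class:`UnitError` and an unknown or undeclared parameter raises
    :class:`SchemaError`.  Required parameters must be covered by entered
    values, fresh prefill, or explicit deferral.  Returns the next page id
    (or ``TERMINAL``) plus the newly emitted cards.
    """
    if session.status != SessionStatus.in_progress:
        raise SessionStateError(f"session is {session.status.value}")
    if session.current_page == TERMINAL:
        raise SessionStateError("session already reached TERMINAL")
    page = session.flow.page(session.current_page)
    values = values or {}
    deferred = deferred or set()
    declared = {rp.code for rp in page.required_parameters}
    for code, raw in values.items():
        try:
            concept = codes.by_code(code)
        except KeyError as exc:
            raise SchemaError(str(exc)) from exc
        if code not in declared:
            raise SchemaError(
                f"parameter {code} is not declared on page {page.page_id}")
        if isinstance(raw, tuple):
            value, unit = raw
            expected = codes.DEFAULT_UNITS.get(concept.key(), "")
            if expected and unit != expected:
                raise UnitError(
                    f"{code} expects unit {expected!r}, got {unit!r}")
        else:
            value = float(raw)
        _record_entered(session, code, value)

    effective = session.effective_values()
    missing = [rp.code for rp in page.required_parameters
               if not rp.optional and rp.code not in effective
               and rp.code not in deferred]
    if missing:
        raise SchemaError(
            f"page {page.page_id} missing required parameters: {missing}")

    new_cards: list[cds_rules.CdsCard] = []
    seen = {c.rule_id for c in session.emitted_cards}
    for rule_id in page.attached_cds_rules:
        for card in _run_rule(session, rule_id):
            if card.rule_id not in seen:
                new_cards.append(card)
                seen.add(card.rule_id)
    # the FPG>110 prompt is evaluated wherever glucose appears, even if the
    # flow does not attach it explicitly
    if codes.FPG.code in values:
        for card in cds_rules.module_transition_check(
                session.effective_values(), session.dataset, session.as_of,
                session.module.module_id, session.track.value):
            if card.rule_id not in seen:
                new_cards.append(card)
                seen.add(card.rule_id)
    session.emitted_cards.extend(new_cards)

    ctx = EvalContext(dataset=session.dataset, as_of=session.as_of,
                      session_values=session.effective_values())
    next_page = None
    for transition in session.flow.transitions_from(page.page_id):
        if transition.predicate is None or transition.predicate.evaluate(ctx)[0]:
            next_page = transition.to_page
            break
    if next_page is None:  # validator guarantees a catch-all; defensive
        raise SessionStateError(f"no transition matched from {page.page_id}")
    session.current_page = next_page
    if next_page != TERMINAL:
        session.visited_pages.append(next_page)
    return next_page, new_cards


_CARD_ACTIVITY = {
    cds_rules.CardKind.lab_order: ActivityKind.lab_order,
    cds_rules.CardKind.referral_suggestion: ActivityKind.referral,
    cds_rules.CardKind.medication_suggestion: ActivityKind.medication_order,
}


def complete_encounter(
    session: EncounterSession,
    performer: str = "",
    duration_minutes: float = 1.0,
    auto_accept_pending: bool = True,
) -> CompletedEncounter:
    """Close a session that has reached TERMINAL.

    Accepted cards (pending cards too, under the default auto-accept
    policy; rejected cards never) become the care plan's goals and
    activities, a mandatory follow-up appointment is added from the
    module's interval rule, the encounter is recorded on the working
    dataset, and the schedules of this module plus any accepted
    transition targets are recomputed.
    """
    if session.status == SessionStatus.completed:
        raise SessionStateError("session already completed")
    if session.current_page != TERMINAL:
        raise SessionStateError(
            f"session is at page {session.current_page!r}, not TERMINAL")

    def included(card: cds_rules.CdsCard) -> bool:
        if card.accepted == cds_rules.Acceptance.rejected:
            return False
        if card.accepted == cds_rules.Acceptance.pending:
            return auto_accept_pending
        return True

    goals: list[GoalRecord] = []
    activities: list[CarePlanActivity] = []
    prompts: list[cds_rules.CdsCard] = []
    follow_up_card = None
    for card in session.emitted_cards:
        if not included(card):
            continue
        if card.kind == cds_rules.CardKind.goal_suggestion:
            goals.append(GoalRecord(
                parameter=card.code,
                comparator=Comparator(card.comparator),
                target_value=card.target,
                unit=card.unit or "",
                set_date=session.as_of,
                set_by=(GoalSetBy.physician_override
                        if card.status == "physician_override"
                        else GoalSetBy.cds_suggested),
            ))
        elif card.kind in _CARD_ACTIVITY:
            activities.append(CarePlanActivity(
                kind=_CARD_ACTIVITY[card.kind],
                payload=card.code,
                text=card.rationale,
                due_date=session.as_of
                if card.kind == cds_rules.CardKind.referral_suggestion else None,
            ))
        elif card.kind == cds_rules.CardKind.diagnosis_suggestion:
            if card.accepted == cds_rules.Acceptance.accepted:
                session.dataset.conditions.append(ConditionEntry(
                    icd10=card.code, onset_date=session.as_of))
        elif card.kind == cds_rules.CardKind.module_transition_prompt:
            prompts.append(card)
        elif card.kind == cds_rules.CardKind.follow_up_suggestion:
            follow_up_card = card

    if follow_up_card is None:
        _, follow_up_card = cds_rules.follow_up_interval(
            session.module, session.track.value, as_of=session.as_of)
    activities.append(CarePlanActivity(
        kind=ActivityKind.follow_up_appointment,
        payload=CodedConcept(system="urn:dmp:module",
                             code=session.module.module_id,
                             display=f"{session.module.display or session.module.module_id} "
                                     f"{session.track.value} follow-up"),
        text=follow_up_card.rationale,
        due_date=follow_up_card.due_date,
    ))

    plan = CarePlanRecord(
        patient_id=session.dataset.patient_id,
        encounter_ref=session.session_id,
        goals=goals,
        activities=activities,
    )
    encounter = EncounterRecord(
        module_id=session.module.module_id,
        encounter_type=EncounterType(session.track.value),
        date=session.as_of,
        performer=performer or session.dataset.patient.assigned_fmp,
        duration_minutes=duration_minutes,
    )
    session.dataset.encounters.append(encounter)
    session.dataset.care_plans.append(plan)
    session.dataset.goals.extend(goals)
    session.status = SessionStatus.completed

    schedule_updates = {
        session.module.module_id: next_due(session.dataset, session.module,
                                           session.as_of)
    }
    from dmpkit.registry import builtin_defaults
    registry = None
    for prompt in prompts:
        target = (prompt.status or "").split(":")[0]
        if not target:
            continue
        if registry is None:
            registry = builtin_defaults()
        if target in registry.modules:
            schedule_updates[target] = next_due(
                session.dataset, registry.module(target), session.as_of)
    return CompletedEncounter(
        care_plan=plan,
        encounter=encounter,
        schedule_updates=schedule_updates,
        transition_prompts=prompts,
        dataset=session.dataset,
    )
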