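"""Pathway engine: flow validation, prefill, transitions, completion."""

import datetime as dt
import random

import pytest

from dmpkit import codes
from dmpkit.cds import CardKind
from dmpkit.model import Freshness, export_care_plan
from dmpkit.pathway import (
    TERMINAL,
    EligibilityError,
    PageDefinition,
    PageFlow,
    SchemaError,
    SessionStateError,
    StepKind,
    Transition,
    UnitError,
    complete_encounter,
    start_encounter,
    submit_page,
    validate_flow,
)
from dmpkit.predicates import p_obs
from dmpkit.validation import validate_care_plan

from conftest import AS_OF, condition, make_patient, medication, observation


# ---------------------------------------------------------------------------
# static flow validation

def test_single_page_flow_is_valid():
    flow = PageFlow(
        flow_id="f", entry_page="only",
        pages=[PageDefinition(page_id="only",
                              step_kind=StepKind.physical_examination)],
        transitions=[Transition(from_page="only", to_page=TERMINAL)])
    assert validate_flow(flow).valid


def test_mutually_cycling_pages_reported_as_nonterminating():
    flow = PageFlow(
        flow_id="f", entry_page="a",
        pages=[PageDefinition(page_id="a", step_kind=StepKind.lab_review),
               PageDefinition(page_id="b", step_kind=StepKind.lab_review)],
        transitions=[Transition(from_page="a", to_page="b"),
                     Transition(from_page="b", to_page="a")])
    report = validate_flow(flow)
    assert not report.valid
    assert report.nonterminating_pages


def test_unreachable_page_reported():
    flow = PageFlow(
        flow_id="f", entry_page="a",
        pages=[PageDefinition(page_id="a", step_kind=StepKind.lab_review),
               PageDefinition(page_id="orphan", step_kind=StepKind.lab_review)],
        transitions=[Transition(from_page="a", to_page=TERMINAL),
                     Transition(from_page="orphan", to_page=TERMINAL)])
    assert validate_flow(flow).unreachable_pages == ["orphan"]


def test_missing_catch_all_reported():
    flow = PageFlow(
        flow_id="f", entry_page="a",
        pages=[PageDefinition(page_id="a", step_kind=StepKind.lab_review)],
        transitions=[Transition(from_page="a",
                                predicate=p_obs(codes.FPG.code, "gt", 110),
                                to_page=TERMINAL)])
    report = validate_flow(flow)
    assert "a" in report.nonterminating_pages


def test_all_shipped_flows_are_valid(registry):
    for flow in registry.flows.values():
        report = validate_flow(flow)
        assert report.valid, report.problems()


# ---------------------------------------------------------------------------
# session lifecycle

def _screening_patient(**extra):
    return make_patient(birth_date=dt.date(1975, 3, 1), **extra)


def test_start_prefills_fresh_parameters(registry):
    ds = _screening_patient(observations=[
        observation(codes.SBP, 128, dt.date(2023, 3, 1)),
        observation(codes.DBP, 82, dt.date(2023, 3, 1)),
    ])
    session = start_encounter(ds, registry.module("hypertension"),
                              "screening", AS_OF, registry=registry)
    assert session.prefill[codes.SBP.code].value == 128
    assert session.prefill[codes.SBP.code].freshness == Freshness.fresh
    assert codes.SBP.code in session.effective_values()


def test_expired_prefill_is_flagged_for_renewal(registry):
    ds = _screening_patient(observations=[
        observation(codes.FPG, 98, dt.date(2021, 1, 1)),  # > 12 months old
    ])
    session = start_encounter(ds, registry.module("hypertension"),
                              "screening", AS_OF, registry=registry)
    assert session.prefill[codes.FPG.code].freshness == Freshness.expired
    assert codes.FPG.code in session.renewal_flags
    assert codes.FPG.code not in session.effective_values()


def test_ineligible_patient_cannot_start(registry):
    diagnosed = make_patient(conditions=[condition("I10")],
                             medications=[medication()])
    with pytest.raises(EligibilityError):
        start_encounter(diagnosed, registry.module("hypertension"),
                        "screening", AS_OF, registry=registry)


def _walk_hypertension_screening(registry, ds, answers):
    session = start_encounter(ds, registry.module("hypertension"),
                              "screening", AS_OF, registry=registry)
    while session.current_page != TERMINAL:
        page = session.flow.page(session.current_page)
        values = answers.get(page.page_id, {})
        needed = {rp.code for rp in page.required_parameters if not rp.optional}
        defaults = {codes.SBP.code: 120.0, codes.DBP.code: 78.0,
                    codes.FPG.code: 95.0}
        for code in needed:
            if code not in values and code not in session.effective_values():
                values[code] = defaults.get(code, 1.0)
        submit_page(session, values)
    return session


def test_fpg_over_110_prompts_diabetes_screening(registry):
    ds = _screening_patient()
    session = _walk_hypertension_screening(
        registry, ds, {"labs": {codes.FPG.code: 120.0}})
    prompts = [c for c in session.emitted_cards
               if c.kind == CardKind.module_transition_prompt]
    assert any(c.rule_id == "fpg-diabetes-prompt" for c in prompts)


def test_fpg_exactly_110_does_not_prompt(registry):
    ds = _screening_patient()
    session = _walk_hypertension_screening(
        registry, ds, {"labs": {codes.FPG.code: 110.0}})
    assert not any(c.rule_id == "fpg-diabetes-prompt"
                   for c in session.emitted_cards)


def test_elevated_bp_routes_through_confirmation_and_diagnosis(registry):
    ds = _screening_patient()
    session = _walk_hypertension_screening(
        registry, ds,
        {"vitals": {codes.SBP.code: 152.0, codes.DBP.code: 96.0},
         "confirm_bp": {codes.SBP.code: 149.0, codes.DBP.code: 94.0}})
    assert "confirm_bp" in session.visited_pages
    assert "diagnosis" in session.visited_pages
    assert any(c.kind == CardKind.diagnosis_suggestion
               and c.code.code == "I10" for c in session.emitted_cards)


def test_normal_bp_skips_confirmation(registry):
    ds = _screening_patient()
    session = _walk_hypertension_screening(registry, ds, {})
    assert "confirm_bp" not in session.visited_pages


def test_wrong_unit_and_unknown_parameter_rejected(registry):
    ds = _screening_patient()
    session = start_encounter(ds, registry.module("hypertension"),
                              "screening", AS_OF, registry=registry)
    with pytest.raises(UnitError):
        submit_page(session, {codes.SBP.code: (120.0, "kPa"),
                              codes.DBP.code: 80.0})
    with pytest.raises(SchemaError):
        submit_page(session, {"not-a-code": 1.0})
    with pytest.raises(SchemaError, match="missing required"):
        submit_page(session, {})


def test_prefill_never_overwrites_entered_value(registry):
    ds = _screening_patient(observations=[
        observation(codes.SBP, 131, dt.date(2023, 5, 1)),
        observation(codes.DBP, 84, dt.date(2023, 5, 1)),
    ])
    session = start_encounter(ds, registry.module("hypertension"),
                              "screening", AS_OF, registry=registry)
    submit_page(session, {codes.SBP.code: 144.0, codes.DBP.code: 90.0})
    assert session.effective_values()[codes.SBP.code] == 144.0


def test_complete_assembles_care_plan_and_updates_schedule(registry):
    ds = _screening_patient(observations=[
        observation(codes.EGFR, 55, dt.date(2023, 4, 1)),
    ])
    session = _walk_hypertension_screening(
        registry, ds, {"labs": {codes.FPG.code: 120.0}})
    result = complete_encounter(session)

    kinds = [a.kind.value for a in result.care_plan.activities]
    assert "referral" in kinds          # eGFR 55 -> nephrology
    assert "follow_up_appointment" in kinds
    follow_up = [a for a in result.care_plan.activities
                 if a.kind.value == "follow_up_appointment"][0]
    assert follow_up.due_date is not None

    # the accepted diabetes prompt leaves the diabetes schedule due now
    assert result.schedule_updates["diabetes"].status.value == "due_now"
    # care plan export of the real output is schema-valid
    assert validate_care_plan(export_care_plan(result.care_plan)) == []


def test_complete_requires_terminal_and_rejects_double_completion(registry):
    ds = _screening_patient()
    session = start_encounter(ds, registry.module("hypertension"),
                              "screening", AS_OF, registry=registry)
    with pytest.raises(SessionStateError):
        complete_encounter(session)
    while session.current_page != TERMINAL:
        page = session.flow.page(session.current_page)
        values = {rp.code: 100.0 for rp in page.required_parameters
                  if not rp.optional}
        submit_page(session, values)
    complete_encounter(session)
    with pytest.raises(SessionStateError):
        complete_encounter(session)


def test_randomized_encounters_terminate_within_page_budget(registry):
    """Sessions over the shipped hypertension flow always reach TERMINAL in
    at most (number of pages) steps, whatever values are entered."""
    rng = random.Random(1234)
    flow = registry.flow("hypertension-screening")
    for i in range(150):
        ds = _screening_patient(patient_id=f"r{i}")
        session = start_encounter(ds, registry.module("hypertension"),
                                  "screening", AS_OF, registry=registry)
        steps = 0
        while session.current_page != TERMINAL:
            page = session.flow.page(session.current_page)
            values = {}
            for rp in page.required_parameters:
                if rp.code == codes.SBP.code:
                    values[rp.code] = rng.uniform(90, 220)
                elif rp.code == codes.DBP.code:
                    values[rp.code] = rng.uniform(50, 130)
                elif rp.code == codes.FPG.code:
                    values[rp.code] = rng.uniform(60, 300)
                elif not rp.optional:
                    values[rp.code] = rng.uniform(1, 100)
            submit_page(session, values)
            steps += 1
            assert steps <= len(flow.pages)
        result = complete_encounter(session)
        assert validate_care_plan(export_care_plan(result.care_plan)) == []
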