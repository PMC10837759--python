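"""CDS rule families: risk scoring oracle, rule boundaries, determinism."""

import datetime as dt
import itertools
import math
import random

import pytest

from dmpkit import codes
from dmpkit.cds import (
    CardKind,
    DEMO_COEFFICIENTS,
    OPHTHALMOLOGY,
    cvd_risk_score,
    follow_up_interval,
    medication_advice,
    module_transition_check,
    recommend_diagnosis,
    recommend_goals,
    referral_advice,
    required_lab_panel,
    risk_score_card,
)
from dmpkit.model import (
    ActivityKind,
    CarePlanActivity,
    CarePlanRecord,
    EncounterRecord,
    EncounterType,
    Sex,
    add_months,
)
from dmpkit.predicates import categorize_risk

from conftest import AS_OF, condition, make_patient, medication, observation


# ---------------------------------------------------------------------------
# risk score: independent re-derivation oracle

def _oracle_risk(age, sex, smoker, sbp, chol):
    """Independent formulation: per-cause risk via the cumulative-hazard
    increment, 1 - exp(-(H(a+10) - H(a)) * e^w) with H(t) = e^a (t-20)^p."""
    total = 0.0
    for coef in (DEMO_COEFFICIENTS.chd[sex], DEMO_COEFFICIENTS.non_chd[sex]):
        w = (coef.beta_smoker * smoker + coef.beta_sbp * (sbp - 120.0)
             + coef.beta_chol * (chol - 6.0))
        h_now = math.exp(coef.alpha) * (age - 20.0) ** coef.p
        h_later = math.exp(coef.alpha) * (age + 10.0 - 20.0) ** coef.p
        total += 1.0 - math.exp(-(h_later - h_now) * math.exp(w))
    return min(total, 1.0) * 100.0


def test_risk_score_matches_independent_oracle_on_grid():
    worst = 0.0
    for age, sex, smoker, sbp, chol in itertools.product(
            (30, 45, 60, 75, 90), (Sex.male, Sex.female), (False, True),
            (100, 120, 160, 200), (4.0, 6.0, 8.0)):
        got = cvd_risk_score(age, sex, smoker, sbp, chol).ten_year_risk_percent
        want = _oracle_risk(age, sex, smoker, sbp, chol)
        worst = max(worst, abs(got - want) / max(want, 1e-12))
    assert worst < 1e-9


def test_risk_score_monotone_in_each_factor():
    base = dict(age=55, sex=Sex.male, smoker=False, sbp=140,
                total_cholesterol=6.0)

    def risk(**over):
        return cvd_risk_score(**{**base, **over}).ten_year_risk_percent

    assert risk(age=65) > risk()
    assert risk(sbp=180) > risk()
    assert risk(total_cholesterol=8.0) > risk()
    assert risk(smoker=True) > risk()


@pytest.mark.parametrize("kwargs", [
    dict(age=29), dict(age=91), dict(sbp=65), dict(sbp=270),
    dict(total_cholesterol=1.5), dict(total_cholesterol=13),
])
def test_risk_score_rejects_out_of_range_inputs(kwargs):
    base = dict(age=55, sex=Sex.male, smoker=False, sbp=140,
                total_cholesterol=6.0)
    with pytest.raises(ValueError, match="outside supported range"):
        cvd_risk_score(**{**base, **kwargs})


def test_risk_category_band_boundaries():
    assert categorize_risk(0.99) == "low"
    assert categorize_risk(1.0) == "moderate"
    assert categorize_risk(4.99) == "moderate"
    assert categorize_risk(5.0) == "high"
    assert categorize_risk(10.0) == "very_high"


def test_risk_card_carries_value_and_category():
    result = cvd_risk_score(70, Sex.male, True, 180, 8.0)
    card = risk_score_card(result)
    assert card.kind == CardKind.risk_score
    assert card.value == result.ten_year_risk_percent
    assert card.status == result.category


# ---------------------------------------------------------------------------
# diagnosis suggestions

def test_hypertension_diagnosis_boundary(registry):
    module = registry.module("hypertension")
    at_threshold = recommend_diagnosis(
        {codes.SBP.code: 140.0, codes.DBP.code: 80.0}, module)
    assert any(c.kind == CardKind.diagnosis_suggestion
               and c.code.code == "I10" for c in at_threshold)
    below = recommend_diagnosis(
        {codes.SBP.code: 139.0, codes.DBP.code: 89.0}, module)
    assert not any(c.kind == CardKind.diagnosis_suggestion for c in below)


def test_missing_required_parameter_yields_lab_order_not_error(registry):
    module = registry.module("hypertension")
    cards = recommend_diagnosis({codes.DBP.code: 80.0}, module)
    orders = [c for c in cards if c.kind == CardKind.lab_order]
    assert [c.code.code for c in orders] == [codes.SBP.code]
    assert all(c.rationale for c in cards)


def test_diabetes_diagnosis_from_fpg(registry):
    module = registry.module("diabetes")
    cards = recommend_diagnosis({codes.FPG.code: 126.0}, module)
    assert any(c.code.code == "E11" for c in cards
               if c.kind == CardKind.diagnosis_suggestion)
    cards = recommend_diagnosis({codes.FPG.code: 125.9}, module)
    assert not any(c.kind == CardKind.diagnosis_suggestion for c in cards)


# ---------------------------------------------------------------------------
# lab-order guidance

def test_lab_panel_orders_absent_and_expired_only(registry):
    module = registry.module("diabetes")
    ds = make_patient(observations=[
        observation(codes.FPG, 100, dt.date(2023, 3, 1)),    # fresh (12m)
        observation(codes.HBA1C, 6.1, dt.date(2022, 6, 1)),  # expired (6m)
    ])
    cards = required_lab_panel(ds, module, AS_OF)
    by_code = {c.code.code: c.status for c in cards}
    assert codes.FPG.code not in by_code
    assert by_code[codes.HBA1C.code] == "expired"
    assert by_code[codes.EGFR.code] == "absent"
    assert set(by_code) <= set(module.lab_panel)


# ---------------------------------------------------------------------------
# goals

def test_goal_policy_keys_on_risk_category(registry):
    module = registry.module("hypertension")
    ds = make_patient()
    default_cards = recommend_goals(ds, module, as_of=AS_OF)
    assert {(c.code.code, c.target) for c in default_cards} == \
        {(codes.SBP.code, 140.0), (codes.DBP.code, 90.0)}

    risk = cvd_risk_score(75, Sex.male, True, 200, 8.0)
    assert risk.category == "very_high"
    tight = recommend_goals(ds, module, risk=risk, as_of=AS_OF)
    assert (codes.LDL.code, 70.0) in {(c.code.code, c.target) for c in tight}


def test_goal_policy_falls_back_to_stored_risk_score(registry):
    module = registry.module("hypertension")
    ds = make_patient(observations=[
        observation(codes.CVD_RISK, 7.0, dt.date(2023, 1, 1))])
    cards = recommend_goals(ds, module, as_of=AS_OF)
    assert (codes.SBP.code, 130.0) in {(c.code.code, c.target) for c in cards}


# ---------------------------------------------------------------------------
# medication advice

def test_contraindication_warning_names_condition(registry):
    module = registry.module("hypertension")
    asthmatic = make_patient(conditions=[condition("J45")])
    cards = medication_advice(asthmatic, module, ["beta_blocker", "thiazide"],
                              AS_OF)
    by_tag = {c.code.display: c for c in cards}
    assert by_tag["beta_blocker"].kind == CardKind.contraindication_warning
    assert "J45" in by_tag["beta_blocker"].rationale
    assert by_tag["thiazide"].kind == CardKind.medication_suggestion


def test_resolved_condition_does_not_contraindicate(registry):
    module = registry.module("hypertension")
    ds = make_patient(conditions=[condition("J45", status="resolved")])
    cards = medication_advice(ds, module, ["beta_blocker"], AS_OF)
    assert cards[0].kind == CardKind.medication_suggestion


def test_medication_advice_matches_table_scan_brute_force(registry):
    """Oracle: a warning appears iff some active condition code starts
    with the contraindication prefix for that class."""
    rng = random.Random(99)
    module = registry.module("hypertension")
    pool = ["J45", "J459", "M10", "M100", "I10", "E11", "K21"]
    tags = ["beta_blocker", "thiazide", "ace_inhibitor"]
    for _ in range(200):
        chosen = rng.sample(pool, rng.randrange(0, 4))
        ds = make_patient(conditions=[condition(c) for c in chosen])
        cards = medication_advice(ds, module, tags, AS_OF)
        assert len(cards) == len(tags)
        for tag, card in zip(tags, cards):
            prefixes = [ci.icd10_prefix for ci in module.contraindications
                        if ci.class_tag == tag]
            expect_warning = any(c.startswith(p) for c in chosen
                                 for p in prefixes)
            got_warning = card.kind == CardKind.contraindication_warning
            assert got_warning == expect_warning, (chosen, tag)


# ---------------------------------------------------------------------------
# referrals

def test_egfr_referral_strictly_below_60(registry):
    module = registry.module("hypertension")
    low = make_patient(observations=[
        observation(codes.EGFR, 55, dt.date(2023, 4, 1))])
    cards = referral_advice(low, module, AS_OF)
    assert [c.code.code for c in cards] == ["referral:nephrology"]

    exactly = make_patient(observations=[
        observation(codes.EGFR, 60, dt.date(2023, 4, 1))])
    assert referral_advice(exactly, module, AS_OF) == []

    stale = make_patient(observations=[
        observation(codes.EGFR, 55, dt.date(2022, 4, 1))])  # 14 months old
    assert referral_advice(stale, module, AS_OF) == []


def _with_eye_referral(ds, due):
    ds.care_plans.append(CarePlanRecord(
        patient_id=ds.patient_id, encounter_ref="enc-x",
        activities=[CarePlanActivity(kind=ActivityKind.referral,
                                     payload=OPHTHALMOLOGY, due_date=due)]))
    return ds


def test_retinopathy_check_due_yearly_during_monitoring(registry):
    module = registry.module("diabetes")
    never = make_patient(conditions=[condition("E11")])
    cards = referral_advice(never, module, AS_OF, track="monitoring")
    assert any(c.code.code == "referral:ophthalmology" for c in cards)

    recent = _with_eye_referral(make_patient(conditions=[condition("E11")]),
                                dt.date(2023, 1, 15))
    cards = referral_advice(recent, module, AS_OF, track="monitoring")
    assert not any(c.code.code == "referral:ophthalmology" for c in cards)

    overdue = _with_eye_referral(make_patient(conditions=[condition("E11")]),
                                 dt.date(2022, 3, 15))  # 14+ months ago
    cards = referral_advice(overdue, module, AS_OF, track="monitoring")
    assert any(c.code.code == "referral:ophthalmology" for c in cards)


def test_retinopathy_check_not_raised_during_screening(registry):
    module = registry.module("diabetes")
    ds = make_patient()
    cards = referral_advice(ds, module, AS_OF, track="screening")
    assert not any(c.code.code == "referral:ophthalmology" for c in cards)


# ---------------------------------------------------------------------------
# follow-up

def test_follow_up_intervals_and_due_date(registry):
    months, card = follow_up_interval(registry.module("cvd_risk"),
                                      "screening", risk_category="low",
                                      as_of=AS_OF)
    assert months == 24 and card.due_date == add_months(AS_OF, 24)
    months, _ = follow_up_interval(registry.module("cvd_risk"),
                                   "screening", risk_category="high")
    assert months == 12
    months, _ = follow_up_interval(registry.module("hypertension"),
                                   "monitoring")
    assert months == 3
    months, _ = follow_up_interval(registry.module("diabetes"), "monitoring",
                                   control_status="controlled")
    assert months == 6


# ---------------------------------------------------------------------------
# module transitions

def _monitored_htn(**extra):
    return make_patient(birth_date=dt.date(1975, 3, 1),
                        conditions=[condition("I10")],
                        medications=[medication()], **extra)


def test_fpg_prompt_only_strictly_above_threshold(registry):
    ds = _monitored_htn()
    prompts = module_transition_check({codes.FPG.code: 111.0}, ds, AS_OF,
                                      "hypertension", "monitoring")
    assert any(c.rule_id == "fpg-diabetes-prompt" for c in prompts)
    prompts = module_transition_check({codes.FPG.code: 110.0}, ds, AS_OF,
                                      "hypertension", "monitoring")
    assert not any(c.rule_id == "fpg-diabetes-prompt" for c in prompts)


def test_fpg_prompt_suppressed_for_known_diabetics_and_inside_module(registry):
    diabetic = _monitored_htn(patient_id="p-dm")
    diabetic.conditions.append(condition("E11"))
    prompts = module_transition_check({codes.FPG.code: 150.0}, diabetic,
                                      AS_OF, "hypertension", "monitoring")
    assert not any(c.rule_id == "fpg-diabetes-prompt" for c in prompts)

    ds = _monitored_htn()
    prompts = module_transition_check({codes.FPG.code: 150.0}, ds, AS_OF,
                                      "diabetes", "monitoring")
    assert not any(c.rule_id == "fpg-diabetes-prompt" for c in prompts)


def test_cvd_prompt_for_over_40_without_score(registry):
    ds = _monitored_htn()
    prompts = module_transition_check({}, ds, AS_OF,
                                      "hypertension", "monitoring")
    assert any(c.rule_id == "cvd-risk-prompt" for c in prompts)

    scored = _monitored_htn(observations=[
        observation(codes.CVD_RISK, 3.0, dt.date(2023, 1, 1))])
    prompts = module_transition_check({}, scored, AS_OF,
                                      "hypertension", "monitoring")
    assert not any(c.rule_id == "cvd-risk-prompt" for c in prompts)

    young = make_patient(birth_date=dt.date(1990, 1, 1),
                         conditions=[condition("I10")],
                         medications=[medication()])
    prompts = module_transition_check({}, young, AS_OF,
                                      "hypertension", "monitoring")
    assert not any(c.rule_id == "cvd-risk-prompt" for c in prompts)


# ---------------------------------------------------------------------------
# determinism

def test_rule_families_are_deterministic(registry):
    module = registry.module("hypertension")
    ds = make_patient(conditions=[condition("J45")], observations=[
        observation(codes.EGFR, 55, dt.date(2023, 4, 1)),
        observation(codes.CVD_RISK, 7.0, dt.date(2023, 1, 1)),
    ])

    def run():
        cards = []
        cards += recommend_diagnosis({codes.SBP.code: 150.0,
                                      codes.DBP.code: 95.0}, module, ds, AS_OF)
        cards += required_lab_panel(ds, module, AS_OF)
        cards += recommend_goals(ds, module, as_of=AS_OF)
        cards += medication_advice(ds, module, ["beta_blocker"], AS_OF)
        cards += referral_advice(ds, module, AS_OF)
        return [c.model_dump() for c in cards]

    assert run() == run()
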