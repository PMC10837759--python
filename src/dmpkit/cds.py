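"""Decision-support rule families.

Every family is a pure function from patient context to a list of
:class:`CdsCard` objects: same inputs, identical cards.  The families
cover risk scoring, diagnosis suggestions, lab-order guidance, treatment
goals, medication advice with contraindication warnings, lab-driven and
preventive referrals, follow-up scheduling, and cross-module transition
prompts.  The CDS Hooks transport wrapper lives in :mod:`dmpkit.hooks`.
"""

from __future__ import annotations

import datetime as dt
import math
from enum import Enum
from typing import Any, Optional

from pydantic import BaseModel, Field, model_validator

from dmpkit import codes
from dmpkit.model import (
    ActivityKind,
    CodedConcept,
    Freshness,
    ICD10,
    LOCAL,
    PatientDataSet,
    PatientRecord,
    Sex,
    add_months,
    latest_observation,
)
from dmpkit.predicates import (
    DEFAULT_RISK_THRESHOLDS,
    EvalContext,
    categorize_risk,
)
from dmpkit.registry import DiseaseModuleDefinition, IntervalRule


class CardKind(str, Enum):
    risk_score = "risk_score"
    diagnosis_suggestion = "diagnosis_suggestion"
    lab_order = "lab_order"
    goal_suggestion = "goal_suggestion"
    medication_suggestion = "medication_suggestion"
    contraindication_warning = "contraindication_warning"
    referral_suggestion = "referral_suggestion"
    follow_up_suggestion = "follow_up_suggestion"
    module_transition_prompt = "module_transition_prompt"


class Acceptance(str, Enum):
    pending = "pending"
    accepted = "accepted"
    rejected = "rejected"


class CdsCard(BaseModel):
    rule_id: str
    kind: CardKind
    code: Optional[CodedConcept] = None
    value: Optional[float] = None
    unit: Optional[str] = None
    comparator: Optional[str] = None
    target: Optional[float] = None
    interval_months: Optional[int] = None
    due_date: Optional[dt.date] = None
    status: Optional[str] = None  # e.g. lab freshness: expired / absent
    rationale: str
    accepted: Acceptance = Acceptance.pending

    @model_validator(mode="after")
    def _rationale_nonempty(self) -> "CdsCard":
        if not self.rationale:
            raise ValueError("card rationale must be non-empty")
        return self


# --------------------------------------------------------------------------
# cardiovascular risk scoring (SCORE functional form)

class CauseCoefficients(BaseModel):
    """Weibull baseline and log-hazard coefficients for one cause stratum."""

    alpha: float
    p: float
    beta_smoker: float
    beta_sbp: float    # per mmHg above 120
    beta_chol: float   # per mmol/L above 6

    @model_validator(mode="after")
    def _finite(self) -> "CauseCoefficients":
        for name in ("alpha", "p", "beta_smoker", "beta_sbp", "beta_chol"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.p <= 0:
            raise ValueError("Weibull shape p must be positive")
        return self


class RiskCoefficientTable(BaseModel):
    calibration: str
    chd: dict[Sex, CauseCoefficients]
    non_chd: dict[Sex, CauseCoefficients]


# Demonstration calibration: the published low-risk-region SCORE
# coefficients.  This is NOT a national calibration; national coefficient
# tables plug in as data.
DEMO_COEFFICIENTS = RiskCoefficientTable(
    calibration="score-2003-low-risk (demonstration)",
    chd={
        Sex.male: CauseCoefficients(alpha=-22.1, p=4.71, beta_smoker=0.71,
                                    beta_sbp=0.018, beta_chol=0.24),
        Sex.female: CauseCoefficients(alpha=-29.8, p=6.36, beta_smoker=0.71,
                                      beta_sbp=0.018, beta_chol=0.24),
    },
    non_chd={
        Sex.male: CauseCoefficients(alpha=-26.7, p=5.64, beta_smoker=0.63,
                                    beta_sbp=0.022, beta_chol=0.02),
        Sex.female: CauseCoefficients(alpha=-31.0, p=6.62, beta_smoker=0.63,
                                      beta_sbp=0.022, beta_chol=0.02),
    },
)


class RiskResult(BaseModel):
    ten_year_risk_percent: float = Field(ge=0, le=100)
    category: str
    inputs_used: dict[str, Any]


def _cause_10yr_risk(coef: CauseCoefficients, age: float, smoker: bool,
                     sbp: float, chol_mmol: float) -> float:
    """10-year risk of a fatal event from one cause stratum.

    Weibull baseline survival S0(t) = exp(-exp(alpha) (t-20)^p), hazard
    scaled by exp(w) with w the linear predictor centred at a non-smoking
    120 mmHg / 6 mmol/L profile; the conditional 10-year risk given
    survival to `age` is 1 - S(age+10)/S(age).
    """
    w = (coef.beta_smoker * (1.0 if smoker else 0.0)
         + coef.beta_sbp * (sbp - 120.0)
         + coef.beta_chol * (chol_mmol - 6.0))
    ew = math.exp(w)

    def survival(t: float) -> float:
        base = math.exp(-math.exp(coef.alpha) * (t - 20.0) ** coef.p)
        return base ** ew

    s_now = survival(age)
    s_later = survival(age + 10.0)
    return 1.0 - s_later / s_now


def cvd_risk_score(
    age: float,
    sex: Sex,
    smoker: bool,
    sbp: float,
    total_cholesterol: float,
    table: RiskCoefficientTable = DEMO_COEFFICIENTS,
    thresholds: Optional[dict[str, float]] = None,
) -> RiskResult:
    """10-year fatal cardiovascular risk (percent) and its category.

    `total_cholesterol` is in mmol/L; `sbp` in mmHg.  CHD and non-CHD
    strata are computed separately and summed, capped at 100%.
    """
    if not 30 <= age <= 90:
        raise ValueError(f"age {age} outside supported range [30, 90]")
    if not 70 <= sbp <= 260:
        raise ValueError(f"systolic BP {sbp} outside supported range [70, 260]")
    if not 2 <= total_cholesterol <= 12:
        raise ValueError(
            f"total cholesterol {total_cholesterol} outside supported range [2, 12]")
    sex = Sex(sex)
    risk = (_cause_10yr_risk(table.chd[sex], age, smoker, sbp, total_cholesterol)
            + _cause_10yr_risk(table.non_chd[sex], age, smoker, sbp,
                               total_cholesterol))
    percent = min(risk, 1.0) * 100.0
    category = categorize_risk(percent, thresholds or DEFAULT_RISK_THRESHOLDS)
    return RiskResult(
        ten_year_risk_percent=percent,
        category=category,
        inputs_used={"age": age, "sex": sex.value, "smoker": smoker,
                     "sbp": sbp, "total_cholesterol": total_cholesterol,
                     "calibration": table.calibration},
    )


def risk_score_card(result: RiskResult, rule_id: str = "score-risk") -> CdsCard:
    return CdsCard(
        rule_id=rule_id,
        kind=CardKind.risk_score,
        code=codes.CVD_RISK,
        value=result.ten_year_risk_percent,
        unit="%",
        status=result.category,
        rationale=(f"10-year fatal cardiovascular risk "
                   f"{result.ten_year_risk_percent:.1f}% "
                   f"({result.category} category)"),
    )


# --------------------------------------------------------------------------
# helpers

def _anonymous_dataset() -> PatientDataSet:
    return PatientDataSet(patient=PatientRecord(
        patient_id="anonymous", birth_date=dt.date(1900, 1, 1),
        sex=Sex.female))


def _ctx(dataset: Optional[PatientDataSet], as_of: Optional[dt.date],
         values: Optional[dict[str, float]] = None) -> EvalContext:
    return EvalContext(dataset=dataset or _anonymous_dataset(),
                       as_of=as_of or dt.date.today(),
                       session_values=values or {})


# --------------------------------------------------------------------------
# diagnosis suggestions

def recommend_diagnosis(
    values: dict[str, float],
    module: DiseaseModuleDefinition,
    dataset: Optional[PatientDataSet] = None,
    as_of: Optional[dt.date] = None,
) -> list[CdsCard]:
    """Diagnosis-suggestion cards from the module's declarative rules.

    Each satisfied diagnostic rule yields one card carrying its ICD-10
    code.  A rule whose required parameters are missing from both the
    entered values and the stored record yields a measurement-request
    card instead of an error.
    """
    ctx = _ctx(dataset, as_of, values)
    cards: list[CdsCard] = []
    for rule in module.cds_rules:
        if rule.family != "diagnosis_suggestion":
            continue
        missing = []
        for code in rule.required_parameters:
            if code in values:
                continue
            if dataset is not None:
                found = latest_observation(ctx.dataset, codes.by_code(code),
                                           ctx.as_of)
                if found.observation is not None:
                    continue
            missing.append(code)
        if missing:
            for code in missing:
                concept = codes.by_code(code)
                cards.append(CdsCard(
                    rule_id=rule.rule_id,
                    kind=CardKind.lab_order,
                    code=concept,
                    status="absent",
                    rationale=(f"{concept.display or code} is required to "
                               f"evaluate rule {rule.rule_id} but has not "
                               f"been measured"),
                ))
            continue
        if rule.predicate is None:
            continue
        truth, reasons = rule.predicate.evaluate(ctx)
        if truth:
            cards.append(CdsCard(
                rule_id=rule.rule_id,
                kind=CardKind.diagnosis_suggestion,
                code=CodedConcept(system=ICD10, code=rule.payload["icd10"],
                                  display=rule.payload.get("display", "")),
                rationale="; ".join(reasons),
            ))
    return cards


# --------------------------------------------------------------------------
# lab-order guidance

def required_lab_panel(
    dataset: PatientDataSet,
    module: DiseaseModuleDefinition,
    as_of: dt.date,
) -> list[CdsCard]:
    """One lab-order card per configured test that is expired or absent."""
    cards: list[CdsCard] = []
    for code in module.lab_panel:
        concept = codes.by_code(code)
        validity = module.validity_periods.get(code)
        found = latest_observation(dataset, concept, as_of, validity)
        if found.freshness == Freshness.fresh:
            continue
        status = found.freshness.value
        if status == "expired":
            rationale = (f"{concept.display or code} last measured "
                         f"{found.observation.effective_date.isoformat()}, "
                         f"older than its {validity}-month validity period")
        else:
            rationale = f"{concept.display or code} has never been measured"
        cards.append(CdsCard(rule_id=f"lab-panel:{code}", kind=CardKind.lab_order,
                             code=concept, status=status, rationale=rationale))
    return cards


# --------------------------------------------------------------------------
# treatment goals

def recommend_goals(
    dataset: PatientDataSet,
    module: DiseaseModuleDefinition,
    risk: Optional[RiskResult] = None,
    as_of: Optional[dt.date] = None,
) -> list[CdsCard]:
    """Goal-suggestion cards from the module's risk-keyed goal policy.

    The policy key is the supplied risk category, else the category
    derived from the stored risk score, else ``default``.
    """
    if not module.goal_policy:
        return []
    key = risk.category if risk is not None \
        else _ctx(dataset, as_of).resolve_risk_category()
    targets = module.goal_policy.get(key or "default",
                                     module.goal_policy.get("default", []))
    cards = []
    for target in targets:
        concept = codes.by_code(target.code)
        cards.append(CdsCard(
            rule_id=f"goal:{module.module_id}:{target.code}",
            kind=CardKind.goal_suggestion,
            code=concept,
            comparator=target.comparator,
            target=target.value,
            unit=target.unit or codes.DEFAULT_UNITS.get(concept.key(), ""),
            rationale=(f"Suggested treatment goal {concept.display or target.code} "
                       f"{target.comparator} {target.value} {target.unit} "
                       f"({key or 'default'} policy)"),
        ))
    return cards


# --------------------------------------------------------------------------
# medication advice

def medication_advice(
    dataset: PatientDataSet,
    module: DiseaseModuleDefinition,
    candidate_classes: list[str],
    as_of: Optional[dt.date] = None,
) -> list[CdsCard]:
    """Suggestion cards for candidate classes, with contraindication
    warnings naming the conflicting active condition."""
    as_of = as_of or dt.date.today()
    cards: list[CdsCard] = []
    for tag in candidate_classes:
        conflict = None
        for contra in module.contraindications:
            if contra.class_tag != tag:
                continue
            for cond in dataset.active_conditions(as_of):
                if cond.icd10.code.startswith(contra.icd10_prefix):
                    conflict = (contra, cond)
                    break
            if conflict:
                break
        concept = CodedConcept(system=LOCAL, code=f"med-class:{tag}", display=tag)
        if conflict:
            contra, cond = conflict
            cards.append(CdsCard(
                rule_id=f"contra:{module.module_id}:{tag}",
                kind=CardKind.contraindication_warning,
                code=concept,
                status=cond.icd10.code,
                rationale=(f"{tag} is contraindicated: active condition "
                           f"{cond.icd10.code} "
                           f"({contra.note or cond.icd10.display})"),
            ))
        else:
            cards.append(CdsCard(
                rule_id=f"med:{module.module_id}:{tag}",
                kind=CardKind.medication_suggestion,
                code=concept,
                rationale=f"{tag} is a candidate class with no recorded "
                          f"contraindicating comorbidity",
            ))
    return cards


# --------------------------------------------------------------------------
# referrals

NEPHROLOGY = CodedConcept(system=LOCAL, code="referral:nephrology",
                          display="Nephrology referral")
OPHTHALMOLOGY = CodedConcept(system=LOCAL, code="referral:ophthalmology",
                             display="Ophthalmology referral")

EGFR_REFERRAL_THRESHOLD = 60.0  # mL/min/1.73m2, strict "below"


def referral_advice(
    dataset: PatientDataSet,
    module: DiseaseModuleDefinition,
    as_of: dt.date,
    track: Optional[str] = None,
) -> list[CdsCard]:
    """Lab-driven and preventive referral cards.

    - A fresh eGFR strictly below 60 mL/min/1.73 m2 yields a nephrology
      referral (exactly 60 does not).
    - During diabetes monitoring, a retinopathy check is due yearly: when
      no ophthalmology referral activity is dated within the past 12
      months, an ophthalmology card is emitted.
    """
    cards: list[CdsCard] = []
    has_egfr_rule = any(r.family == "referral_suggestion"
                        and r.payload.get("specialty") == "nephrology"
                        for r in module.cds_rules)
    if has_egfr_rule:
        validity = module.validity_periods.get(codes.EGFR.code, 12)
        found = latest_observation(dataset, codes.EGFR, as_of, validity)
        if (found.observation is not None
                and found.freshness == Freshness.fresh
                and found.observation.value < EGFR_REFERRAL_THRESHOLD):
            cards.append(CdsCard(
                rule_id="egfr-nephrology",
                kind=CardKind.referral_suggestion,
                code=NEPHROLOGY,
                value=found.observation.value,
                unit="mL/min/1.73m2",
                rationale=(f"eGFR {found.observation.value:g} mL/min/1.73m2 is "
                           f"below {EGFR_REFERRAL_THRESHOLD:g}; nephrology "
                           f"referral recommended"),
            ))
    for rule in module.cds_rules:
        if rule.family != "preventive_referral":
            continue
        if track is not None and track != "monitoring":
            continue
        interval = int(rule.payload.get("interval_months", 12))
        cutoff = add_months(as_of, -interval)
        recent = False
        for plan in dataset.care_plans:
            for act in plan.activities:
                if (act.kind == ActivityKind.referral
                        and act.payload.key() == OPHTHALMOLOGY.key()
                        and act.due_date is not None
                        and cutoff <= act.due_date <= as_of):
                    recent = True
        if not recent:
            cards.append(CdsCard(
                rule_id=rule.rule_id,
                kind=CardKind.referral_suggestion,
                code=OPHTHALMOLOGY,
                interval_months=interval,
                rationale=(f"No retinopathy check recorded within the past "
                           f"{interval} months; yearly ophthalmology review "
                           f"is advised during diabetes monitoring"),
            ))
    return cards


# --------------------------------------------------------------------------
# follow-up scheduling

def follow_up_interval(
    module: DiseaseModuleDefinition,
    track: str,
    risk_category: Optional[str] = None,
    control_status: Optional[str] = None,
    as_of: Optional[dt.date] = None,
) -> tuple[int, CdsCard]:
    """Recall interval in months plus the follow-up card carrying the
    due date (when `as_of` is given).  Unknown context keys fall back to
    the rule's default."""
    rule: IntervalRule = module.interval_rule(track)
    context = risk_category if risk_category in rule.by_context else control_status
    months = rule.interval_for(context)
    due = add_months(as_of, months) if as_of else None
    card = CdsCard(
        rule_id=f"follow-up:{module.module_id}:{track}",
        kind=CardKind.follow_up_suggestion,
        interval_months=months,
        due_date=due,
        rationale=(f"Next {module.module_id} {track} encounter in {months} "
                   f"months" + (f" (due {due.isoformat()})" if due else "")),
    )
    return months, card


# --------------------------------------------------------------------------
# cross-module transitions

FPG_TRANSITION_THRESHOLD = 110.0  # mg/dL, strict "exceeds"


def module_transition_check(
    values: dict[str, float],
    dataset: PatientDataSet,
    as_of: dt.date,
    current_module: str,
    current_track: str,
) -> list[CdsCard]:
    """Prompts to continue into another disease module.

    - Fasting plasma glucose strictly above 110 mg/dL, for a patient not
      already monitored for diabetes (no active E10–E14 diagnosis and no
      prior diabetes monitoring encounter), prompts a diabetes screening.
    - A patient strictly over 40 with no recorded cardiovascular risk
      score prompts the cardiovascular-risk module during hypertension or
      diabetes monitoring encounters.
    """
    from dmpkit.eligibility import age_at

    cards: list[CdsCard] = []
    fpg = values.get(codes.FPG.code)
    if fpg is None:
        found = latest_observation(dataset, codes.FPG, as_of)
        fpg = found.observation.value if found.observation else None
    if fpg is not None and fpg > FPG_TRANSITION_THRESHOLD:
        already_monitored = (
            dataset.has_condition_prefix("E1", as_of)
            or any(e.module_id == "diabetes"
                   and e.encounter_type.value == "monitoring"
                   and e.date <= as_of
                   for e in dataset.encounters))
        if not already_monitored and current_module != "diabetes":
            cards.append(CdsCard(
                rule_id="fpg-diabetes-prompt",
                kind=CardKind.module_transition_prompt,
                code=codes.FPG,
                value=fpg,
                unit="mg/dL",
                status="diabetes:screening",
                rationale=(f"Fasting plasma glucose {fpg:g} mg/dL exceeds "
                           f"{FPG_TRANSITION_THRESHOLD:g}; consider a diabetes "
                           f"screening encounter"),
            ))
    if (current_track == "monitoring"
            and current_module in ("hypertension", "diabetes")
            and age_at(dataset.patient.birth_date, as_of) > 40):
        has_score = latest_observation(dataset, codes.CVD_RISK,
                                       as_of).observation is not None
        if not has_score and codes.CVD_RISK.code not in values:
            cards.append(CdsCard(
                rule_id="cvd-risk-prompt",
                kind=CardKind.module_transition_prompt,
                code=codes.CVD_RISK,
                status="cvd_risk:screening",
                rationale=("Patient is over 40 with no recorded cardiovascular "
                           "risk score; continue with the cardiovascular risk "
                           "module"),
            ))
    return cards
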