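"""Declarative disease-module registry.

Each disease module bundles everything the engines need: eligibility
predicates for the screening and monitoring tracks, recall-interval
rules, parameter validity periods, a page flow, and the decision-support
rule descriptors the CDS layer consumes.  Modules load from YAML/JSON
documents; :func:`builtin_defaults` ships definitions encoding the
national programme's stated rules (diabetes screening every 36 months
over age 40 without a diabetes diagnosis; hypertension monitoring every
3 months on diagnosis plus antihypertensive medication; cardiovascular
risk screening every 24 months for low-risk and 12 for high-risk
citizens; advanced-obesity routing out of the primary-care monitoring
list), with the remaining intervals and criteria as package defaults.
"""

from __future__ import annotations

from typing import Any, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from dmpkit import codes
from dmpkit.flows import (
    TERMINAL,
    FlowValidationReport,
    PageDefinition,
    PageFlow,
    RequiredParameter,
    StepKind,
    Transition,
    validate_flow,
)
from dmpkit.predicates import (
    PredicateExpr,
    p_age,
    p_and,
    p_condition,
    p_const,
    p_medication,
    p_not,
    p_obs,
    p_or,
    p_risk,
)

REGISTRY_VERSION = 1


class RegistryValidationError(ValueError):
    """All problems found while validating a registry, in one exception."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


class IntervalRule(BaseModel):
    """Recall interval in months, keyed by context (risk category, control
    status, ...) with a mandatory ``default`` key."""

    by_context: dict[str, int]

    @field_validator("by_context")
    @classmethod
    def _check(cls, v: dict[str, int]) -> dict[str, int]:
        if "default" not in v:
            raise ValueError("interval rule requires a 'default' key")
        for key, months in v.items():
            if months <= 0:
                raise ValueError(f"interval for {key!r} must be positive")
        return v

    def interval_for(self, context: Optional[str] = None) -> int:
        if context is not None and context in self.by_context:
            return self.by_context[context]
        return self.by_context["default"]


class CdsRuleDescriptor(BaseModel):
    """One declarative decision-support rule attached to a module.

    ``family`` selects the rule family in :mod:`dmpkit.cds`; ``predicate``
    (when present) gates the rule; ``payload`` carries the coded output
    (e.g. an ICD-10 code for a diagnosis suggestion, a specialty for a
    referral).
    """

    rule_id: str
    family: str
    predicate: Optional[PredicateExpr] = None
    required_parameters: list[str] = Field(default_factory=list)
    payload: dict[str, Any] = Field(default_factory=dict)


class Contraindication(BaseModel):
    class_tag: str
    icd10_prefix: str
    note: str = ""


class GoalTarget(BaseModel):
    code: str                      # parameter code
    comparator: str                # le / ge / lt / gt
    value: float
    unit: str = ""


class DiseaseModuleDefinition(BaseModel):
    module_id: str
    display: str = ""
    screening_eligibility: PredicateExpr
    monitoring_eligibility: PredicateExpr
    screening_interval: IntervalRule
    monitoring_interval: IntervalRule
    validity_periods: dict[str, int] = Field(default_factory=dict)
    flow_ref: str
    monitoring_flow_ref: Optional[str] = None  # defaults to flow_ref
    cds_rules: list[CdsRuleDescriptor] = Field(default_factory=list)
    contraindications: list[Contraindication] = Field(default_factory=list)
    # goal targets keyed by risk category ("default" mandatory fallback)
    goal_policy: dict[str, list[GoalTarget]] = Field(default_factory=dict)
    lab_panel: list[str] = Field(default_factory=list)

    @field_validator("validity_periods")
    @classmethod
    def _positive(cls, v: dict[str, int]) -> dict[str, int]:
        for code, months in v.items():
            if months <= 0:
                raise ValueError(f"validity period for {code!r} must be positive")
        return v

    def flow_for(self, track: str) -> str:
        if track == "monitoring" and self.monitoring_flow_ref:
            return self.monitoring_flow_ref
        return self.flow_ref

    def interval_rule(self, track: str) -> IntervalRule:
        return self.screening_interval if track == "screening" \
            else self.monitoring_interval


class ModuleRegistry(BaseModel):
    registry_version: int = REGISTRY_VERSION
    modules: dict[str, DiseaseModuleDefinition] = Field(default_factory=dict)
    flows: dict[str, PageFlow] = Field(default_factory=dict)

    def module(self, module_id: str) -> DiseaseModuleDefinition:
        return self.modules[module_id]

    def flow(self, flow_id: str) -> PageFlow:
        return self.flows[flow_id]

    def validate_registry(self) -> list[str]:
        problems: list[str] = []
        for mid, mod in self.modules.items():
            for ref in {mod.flow_ref, mod.monitoring_flow_ref or mod.flow_ref}:
                if ref not in self.flows:
                    problems.append(f"module {mid}: dangling flow_ref {ref!r}")
        for fid, flow in self.flows.items():
            report = validate_flow(flow)
            problems += [f"flow {fid}: {p}" for p in report.problems()]
        return problems


# --------------------------------------------------------------------------
# serialization

def serialize_registry(registry: ModuleRegistry) -> dict:
    """Registry as one plain config document (YAML/JSON compatible)."""
    return registry.model_dump(mode="json", exclude_none=True)


def load_registry(documents: list[dict]) -> ModuleRegistry:
    """Build and fully validate a registry from parsed config documents.

    Each document may carry ``modules`` (mapping or list) and ``flows``.
    All validation problems are collected and raised together.
    """
    modules: dict[str, DiseaseModuleDefinition] = {}
    flows: dict[str, PageFlow] = {}
    problems: list[str] = []
    version = REGISTRY_VERSION
    for doc in documents:
        version = doc.get("registry_version", version)
        raw_modules = doc.get("modules", {})
        if isinstance(raw_modules, list):
            raw_modules = {m["module_id"]: m for m in raw_modules}
        for mid, raw in raw_modules.items():
            try:
                modules[mid] = DiseaseModuleDefinition.model_validate(raw)
            except Exception as exc:
                problems.append(f"module {mid}: {exc}")
        raw_flows = doc.get("flows", {})
        if isinstance(raw_flows, list):
            raw_flows = {f["flow_id"]: f for f in raw_flows}
        for fid, raw in raw_flows.items():
            try:
                flows[fid] = PageFlow.model_validate(raw)
            except Exception as exc:
                problems.append(f"flow {fid}: {exc}")
    registry = ModuleRegistry(registry_version=version, modules=modules,
                              flows=flows)
    problems += registry.validate_registry()
    if problems:
        raise RegistryValidationError(problems)
    return registry


def load_registry_files(paths: list[str]) -> ModuleRegistry:
    docs = []
    for path in paths:
        with open(path, "r", encoding="utf-8") as fh:
            docs.append(yaml.safe_load(fh))
    return load_registry(docs)


# --------------------------------------------------------------------------
# built-in defaults

ANTIHYPERTENSIVE = "antihypertensive"
ANTIDIABETIC = "antidiabetic"

# ICD-10 prefixes: E10–E14 diabetes, I10–I15 hypertensive diseases, E66 obesity
DIABETES_PREFIX = "E1"
HYPERTENSION_PREFIX = "I1"
OBESITY_PREFIX = "E66"

_SBP, _DBP, _FPG = codes.SBP.code, codes.DBP.code, codes.FPG.code
_HBA1C, _EGFR, _BMI = codes.HBA1C.code, codes.EGFR.code, codes.BMI.code
_LDL, _HDL, _TG = codes.LDL.code, codes.HDL.code, codes.TRIGLYCERIDE.code
_TC, _WEIGHT, _HEIGHT = codes.TOTAL_CHOLESTEROL.code, codes.WEIGHT.code, codes.HEIGHT.code
_WAIST, _RISK, _SMOKER = codes.WAIST.code, codes.CVD_RISK.code, codes.SMOKER.code


def _no_condition(prefix: str) -> PredicateExpr:
    return p_not(p_condition(prefix))


def _advanced_obesity() -> PredicateExpr:
    """Secondary/tertiary-care criteria: BMI > 40, or BMI in (30, 40] with a
    configured comorbidity (diabetes or hypertensive disease by default)."""
    return p_or(
        p_obs(_BMI, "gt", 40),
        p_and(p_obs(_BMI, "gt", 30),
              p_or(p_condition(DIABETES_PREFIX), p_condition(HYPERTENSION_PREFIX))),
    )


def _hypertension_flow() -> PageFlow:
    """Hypertension screening page flow.

    Encodes the elements the pathway is known to contain — blood-pressure
    measurement with a confirmatory re-measurement when elevated, a
    fasting-glucose check with a diabetes-module prompt above 110 mg/dL,
    a diagnosis suggestion step, and follow-up planning.  The remainder of
    the operational flow is illustrative configuration.
    """
    return PageFlow(
        flow_id="hypertension-screening",
        entry_page="vitals",
        pages=[
            PageDefinition(
                page_id="vitals",
                step_kind=StepKind.physical_examination,
                required_parameters=[
                    RequiredParameter(code=_SBP, validity_months=6),
                    RequiredParameter(code=_DBP, validity_months=6),
                    RequiredParameter(code=_WEIGHT, validity_months=12,
                                      optional=True),
                    RequiredParameter(code=_BMI, validity_months=12,
                                      optional=True),
                ],
            ),
            PageDefinition(
                page_id="confirm_bp",
                step_kind=StepKind.physical_examination,
                required_parameters=[
                    RequiredParameter(code=_SBP, prefill=False),
                    RequiredParameter(code=_DBP, prefill=False),
                ],
            ),
            PageDefinition(
                page_id="diagnosis",
                step_kind=StepKind.diagnosis,
                attached_cds_rules=["htn-diagnosis"],
            ),
            PageDefinition(
                page_id="labs",
                step_kind=StepKind.lab_review,
                required_parameters=[
                    RequiredParameter(code=_FPG, validity_months=12),
                    RequiredParameter(code=_EGFR, validity_months=12,
                                      optional=True),
                ],
                attached_cds_rules=["fpg-diabetes-prompt", "egfr-nephrology"],
            ),
            PageDefinition(
                page_id="plan",
                step_kind=StepKind.goal_setting,
                attached_cds_rules=["htn-goals", "htn-follow-up"],
            ),
        ],
        transitions=[
            Transition(from_page="vitals",
                       predicate=p_or(p_obs(_SBP, "ge", 140),
                                      p_obs(_DBP, "ge", 90)),
                       to_page="confirm_bp"),
            Transition(from_page="vitals", to_page="labs"),
            Transition(from_page="confirm_bp",
                       predicate=p_or(p_obs(_SBP, "ge", 140),
                                      p_obs(_DBP, "ge", 90)),
                       to_page="diagnosis"),
            Transition(from_page="confirm_bp", to_page="labs"),
            Transition(from_page="diagnosis", to_page="labs"),
            Transition(from_page="labs", to_page="plan"),
            Transition(from_page="plan", to_page=TERMINAL),
        ],
    )


def _simple_flow(flow_id: str, step_kind: StepKind,
                 params: list[RequiredParameter],
                 page_rules: list[str], plan_rules: list[str]) -> PageFlow:
    return PageFlow(
        flow_id=flow_id,
        entry_page="assessment",
        pages=[
            PageDefinition(page_id="assessment", step_kind=step_kind,
                           required_parameters=params,
                           attached_cds_rules=page_rules),
            PageDefinition(page_id="plan", step_kind=StepKind.goal_setting,
                           attached_cds_rules=plan_rules),
        ],
        transitions=[
            Transition(from_page="assessment", to_page="plan"),
            Transition(from_page="plan", to_page=TERMINAL),
        ],
    )


def builtin_defaults() -> ModuleRegistry:
    """The five shipped disease modules with their stated rules.

    In-programme rules encoded here:

    - diabetes screening: age strictly over 40, no active E10–E14
      diagnosis, recall every 36 months;
    - hypertension monitoring: active I10–I15 diagnosis and ongoing
      antihypertensive medication, recall every 3 months;
    - cardiovascular-risk screening recall: 24 months at low risk,
      12 months at high (or very high) risk;
    - obesity monitoring in primary care only below the advanced-obesity
      criteria (BMI > 40, or BMI in (30, 40] with comorbidities).

    Every other interval/criterion is a package configuration default,
    replaceable via :func:`load_registry`.
    """
    common_validity = {
        _SBP: 6, _DBP: 6, _FPG: 12, _HBA1C: 6, _EGFR: 12,
        _LDL: 12, _HDL: 12, _TG: 12, _TC: 12,
        _WEIGHT: 12, _HEIGHT: 60, _BMI: 12, _WAIST: 12, _RISK: 12,
    }

    hypertension = DiseaseModuleDefinition(
        module_id="hypertension",
        display="Hypertension",
        screening_eligibility=p_and(
            p_age("ge", 18), _no_condition(HYPERTENSION_PREFIX)),
        monitoring_eligibility=p_and(
            p_condition(HYPERTENSION_PREFIX), p_medication(ANTIHYPERTENSIVE)),
        screening_interval=IntervalRule(by_context={"default": 12}),
        monitoring_interval=IntervalRule(by_context={"default": 3}),
        validity_periods=common_validity,
        flow_ref="hypertension-screening",
        cds_rules=[
            CdsRuleDescriptor(
                rule_id="htn-diagnosis", family="diagnosis_suggestion",
                predicate=p_or(p_obs(_SBP, "ge", 140), p_obs(_DBP, "ge", 90)),
                required_parameters=[_SBP, _DBP],
                payload={"icd10": "I10",
                         "display": "Essential (primary) hypertension"}),
            CdsRuleDescriptor(
                rule_id="fpg-diabetes-prompt", family="module_transition",
                predicate=p_obs(_FPG, "gt", 110),
                payload={"target_module": "diabetes", "track": "screening"}),
            CdsRuleDescriptor(
                rule_id="egfr-nephrology", family="referral_suggestion",
                predicate=p_obs(_EGFR, "lt", 60, validity_months=12),
                payload={"specialty": "nephrology"}),
            CdsRuleDescriptor(
                rule_id="htn-goals", family="goal_suggestion"),
            CdsRuleDescriptor(
                rule_id="htn-follow-up", family="follow_up_suggestion"),
        ],
        contraindications=[
            Contraindication(class_tag="beta_blocker", icd10_prefix="J45",
                             note="asthma"),
            Contraindication(class_tag="thiazide", icd10_prefix="M10",
                             note="gout"),
        ],
        goal_policy={
            "default": [
                GoalTarget(code=_SBP, comparator="le", value=140, unit="mmHg"),
                GoalTarget(code=_DBP, comparator="le", value=90, unit="mmHg"),
            ],
            "high": [
                GoalTarget(code=_SBP, comparator="le", value=130, unit="mmHg"),
                GoalTarget(code=_DBP, comparator="le", value=80, unit="mmHg"),
                GoalTarget(code=_LDL, comparator="le", value=100, unit="mg/dL"),
            ],
            "very_high": [
                GoalTarget(code=_SBP, comparator="le", value=130, unit="mmHg"),
                GoalTarget(code=_DBP, comparator="le", value=80, unit="mmHg"),
                GoalTarget(code=_LDL, comparator="le", value=70, unit="mg/dL"),
            ],
        },
        lab_panel=[_FPG, _EGFR, _LDL, _HDL, _TG],
    )

    diabetes = DiseaseModuleDefinition(
        module_id="diabetes",
        display="Diabetes",
        screening_eligibility=p_and(
            p_age("gt", 40), _no_condition(DIABETES_PREFIX)),
        monitoring_eligibility=p_condition(DIABETES_PREFIX),
        screening_interval=IntervalRule(by_context={"default": 36}),
        monitoring_interval=IntervalRule(by_context={"default": 3,
                                                     "controlled": 6}),
        validity_periods=common_validity,
        flow_ref="diabetes-generic",
        cds_rules=[
            CdsRuleDescriptor(
                rule_id="dm-diagnosis", family="diagnosis_suggestion",
                predicate=p_or(p_obs(_FPG, "ge", 126), p_obs(_HBA1C, "ge", 6.5)),
                required_parameters=[_FPG],
                payload={"icd10": "E11",
                         "display": "Type 2 diabetes mellitus"}),
            CdsRuleDescriptor(
                rule_id="dm-retinopathy", family="preventive_referral",
                payload={"specialty": "ophthalmology", "interval_months": 12}),
            CdsRuleDescriptor(
                rule_id="egfr-nephrology", family="referral_suggestion",
                predicate=p_obs(_EGFR, "lt", 60, validity_months=12),
                payload={"specialty": "nephrology"}),
            CdsRuleDescriptor(rule_id="dm-goals", family="goal_suggestion"),
            CdsRuleDescriptor(rule_id="dm-follow-up",
                              family="follow_up_suggestion"),
        ],
        contraindications=[
            Contraindication(class_tag="metformin", icd10_prefix="N18",
                             note="advanced chronic kidney disease"),
        ],
        goal_policy={
            "default": [
                GoalTarget(code=_HBA1C, comparator="le", value=7.0, unit="%"),
                GoalTarget(code=_FPG, comparator="le", value=130, unit="mg/dL"),
            ],
        },
        lab_panel=[_FPG, _HBA1C, _EGFR, _LDL],
    )

    cvd_risk = DiseaseModuleDefinition(
        module_id="cvd_risk",
        display="Cardiovascular risk",
        # high-risk citizens remain on intensified (yearly) screening; only
        # the very-high category moves to the monitoring programme
        screening_eligibility=p_and(p_age("gt", 40), p_not(p_risk("very_high"))),
        monitoring_eligibility=p_risk("very_high"),
        screening_interval=IntervalRule(
            by_context={"default": 24, "low": 24, "moderate": 24,
                        "high": 12, "very_high": 12}),
        monitoring_interval=IntervalRule(by_context={"default": 12}),
        validity_periods=common_validity,
        flow_ref="cvd-risk-generic",
        cds_rules=[
            CdsRuleDescriptor(rule_id="score-risk", family="risk_score"),
            CdsRuleDescriptor(rule_id="cvd-goals", family="goal_suggestion"),
            CdsRuleDescriptor(rule_id="cvd-follow-up",
                              family="follow_up_suggestion"),
        ],
        goal_policy={
            "default": [
                GoalTarget(code=_LDL, comparator="le", value=116, unit="mg/dL"),
            ],
            "high": [
                GoalTarget(code=_LDL, comparator="le", value=100, unit="mg/dL"),
            ],
            "very_high": [
                GoalTarget(code=_LDL, comparator="le", value=70, unit="mg/dL"),
            ],
        },
        lab_panel=[_TC, _LDL, _HDL, _TG],
    )

    obesity = DiseaseModuleDefinition(
        module_id="obesity",
        display="Obesity",
        screening_eligibility=p_and(p_age("ge", 18), _no_condition(OBESITY_PREFIX)),
        monitoring_eligibility=p_and(p_condition(OBESITY_PREFIX),
                                     p_not(_advanced_obesity())),
        screening_interval=IntervalRule(by_context={"default": 12}),
        monitoring_interval=IntervalRule(by_context={"default": 3}),
        validity_periods=common_validity,
        flow_ref="obesity-generic",
        cds_rules=[
            CdsRuleDescriptor(
                rule_id="ob-diagnosis", family="diagnosis_suggestion",
                predicate=p_obs(_BMI, "ge", 30),
                required_parameters=[_BMI],
                payload={"icd10": "E66", "display": "Obesity"}),
            CdsRuleDescriptor(rule_id="ob-goals", family="goal_suggestion"),
            CdsRuleDescriptor(rule_id="ob-follow-up",
                              family="follow_up_suggestion"),
        ],
        goal_policy={
            "default": [
                GoalTarget(code=_BMI, comparator="lt", value=30, unit="kg/m2"),
                GoalTarget(code=_WAIST, comparator="le", value=102, unit="cm"),
            ],
        },
        lab_panel=[_FPG, _LDL],
    )

    older_adult = DiseaseModuleDefinition(
        module_id="older_adult",
        display="Older adult",
        screening_eligibility=p_const(False),  # monitoring-only module
        monitoring_eligibility=p_age("ge", 65),
        screening_interval=IntervalRule(by_context={"default": 12}),
        monitoring_interval=IntervalRule(by_context={"default": 12}),
        validity_periods=common_validity,
        flow_ref="older-adult-generic",
        cds_rules=[
            CdsRuleDescriptor(rule_id="oa-follow-up",
                              family="follow_up_suggestion"),
        ],
        lab_panel=[_FPG, _EGFR],
    )

    flows = {
        "hypertension-screening": _hypertension_flow(),
        "diabetes-generic": _simple_flow(
            "diabetes-generic", StepKind.lab_review,
            [RequiredParameter(code=_FPG, validity_months=12),
             RequiredParameter(code=_HBA1C, validity_months=6, optional=True)],
            ["dm-diagnosis", "dm-retinopathy", "egfr-nephrology"],
            ["dm-goals", "dm-follow-up"]),
        "cvd-risk-generic": _simple_flow(
            "cvd-risk-generic", StepKind.risk_assessment,
            [RequiredParameter(code=_SBP, validity_months=6),
             RequiredParameter(code=_TC, validity_months=12),
             RequiredParameter(code=_SMOKER, validity_months=12)],
            ["score-risk"],
            ["cvd-goals", "cvd-follow-up"]),
        "obesity-generic": _simple_flow(
            "obesity-generic", StepKind.physical_examination,
            [RequiredParameter(code=_WEIGHT, validity_months=12),
             RequiredParameter(code=_HEIGHT, validity_months=60),
             RequiredParameter(code=_BMI, validity_months=12)],
            ["ob-diagnosis"],
            ["ob-goals", "ob-follow-up"]),
        "older-adult-generic": _simple_flow(
            "older-adult-generic", StepKind.scaled_assessment,
            [RequiredParameter(code=_WEIGHT, validity_months=12,
                               optional=True)],
            [],
            ["oa-follow-up"]),
    }

    registry = ModuleRegistry(
        modules={
            "hypertension": hypertension,
            "diabetes": diabetes,
            "cvd_risk": cvd_risk,
            "obesity": obesity,
            "older_adult": older_adult,
        },
        flows=flows,
    )
    problems = registry.validate_registry()
    if problems:  # pragma: no cover - defaults are validated by tests
        raise RegistryValidationError(problems)
    return registry


def dump_registry_yaml(registry: ModuleRegistry) -> str:
    return yaml.safe_dump(serialize_registry(registry), sort_keys=True)
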