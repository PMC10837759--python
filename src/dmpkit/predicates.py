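"""Declarative predicate expressions over patient state.

A :class:`PredicateExpr` is a finite tree of atoms combined with
and/or/not.  The same expression language drives module eligibility
(evaluated against a patient's longitudinal record) and page-flow
transitions (evaluated against values entered during an encounter:
in-session values take precedence over stored observations).

Atoms:

- ``const``: fixed boolean (used e.g. for modules with no screening arm)
- ``age_cmp``: completed age at the evaluation date vs a year threshold
- ``has_condition``: any active condition whose ICD-10 code starts with
  a prefix (e.g. ``"E1"`` covers E10–E14 at onset before the date)
- ``on_medication_class``: any medication with the tag ongoing at the date
- ``observation_cmp``: the freshest in-validity value of a parameter vs a
  threshold; an absent or expired value makes the atom false
- ``has_prior_encounter``: a completed encounter of a module/track within
  a window
- ``risk_category_is``: the patient's cardiovascular risk category
"""

from __future__ import annotations

import datetime as dt
import operator
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from dmpkit import codes
from dmpkit.model import (
    EncounterType,
    Freshness,
    PatientDataSet,
    add_months,
    latest_observation,
)

_OPS = {
    "lt": operator.lt,
    "le": operator.le,
    "gt": operator.gt,
    "ge": operator.ge,
    "eq": operator.eq,
}

# Conventional risk-band cut points on 10-year fatal CVD risk (percent):
# <1 low, 1–<5 moderate, 5–<10 high, >=10 very high.  Configurable.
DEFAULT_RISK_THRESHOLDS = {"moderate": 1.0, "high": 5.0, "very_high": 10.0}


def categorize_risk(percent: float,
                    thresholds: Optional[dict] = None) -> str:
    th = thresholds or DEFAULT_RISK_THRESHOLDS
    if percent >= th["very_high"]:
        return "very_high"
    if percent >= th["high"]:
        return "high"
    if percent >= th["moderate"]:
        return "moderate"
    return "low"


class EvalContext(BaseModel):
    """Everything an atom may consult."""

    dataset: PatientDataSet
    as_of: dt.date
    risk_category: Optional[str] = None
    session_values: dict[str, float] = Field(default_factory=dict)

    def resolve_risk_category(self) -> Optional[str]:
        if self.risk_category is not None:
            return self.risk_category
        found = latest_observation(self.dataset, codes.CVD_RISK, self.as_of)
        if found.observation is None:
            return None
        return categorize_risk(found.observation.value)


AtomKind = Literal[
    "and", "or", "not", "const", "age_cmp", "has_condition",
    "on_medication_class", "observation_cmp", "has_prior_encounter",
    "risk_category_is",
]


class PredicateExpr(BaseModel):
    kind: AtomKind
    args: list["PredicateExpr"] = Field(default_factory=list)
    # atom payload fields (which apply depends on kind)
    value: Optional[bool] = None            # const
    op: Optional[str] = None                # age_cmp / observation_cmp
    years: Optional[int] = None             # age_cmp
    icd10_prefix: Optional[str] = None      # has_condition
    tag: Optional[str] = None               # on_medication_class
    code: Optional[str] = None              # observation_cmp (parameter code)
    threshold: Optional[float] = None       # observation_cmp
    validity_months: Optional[int] = None   # observation_cmp
    module: Optional[str] = None            # has_prior_encounter
    track: Optional[str] = None             # has_prior_encounter
    within_months: Optional[int] = None     # has_prior_encounter
    level: Optional[str] = None             # risk_category_is

    @model_validator(mode="after")
    def _check_shape(self) -> "PredicateExpr":
        k = self.kind
        if k in ("and", "or") and not self.args:
            raise ValueError(f"{k} requires at least one argument")
        if k == "not" and len(self.args) != 1:
            raise ValueError("not requires exactly one argument")
        if k == "const" and self.value is None:
            raise ValueError("const requires a value")
        if k == "age_cmp" and (self.op not in _OPS or self.years is None):
            raise ValueError("age_cmp requires op and years")
        if k == "has_condition" and not self.icd10_prefix:
            raise ValueError("has_condition requires an icd10_prefix")
        if k == "on_medication_class" and not self.tag:
            raise ValueError("on_medication_class requires a tag")
        if k == "observation_cmp":
            if self.op not in _OPS or self.code is None or self.threshold is None:
                raise ValueError("observation_cmp requires code, op, threshold")
            codes.by_code(self.code)  # raises on unresolvable code
        if k == "has_prior_encounter" and (self.module is None or self.track is None):
            raise ValueError("has_prior_encounter requires module and track")
        if k == "risk_category_is" and self.level not in (
                "low", "moderate", "high", "very_high"):
            raise ValueError("risk_category_is requires a valid level")
        return self

    # -- evaluation --------------------------------------------------------

    def evaluate(self, ctx: EvalContext) -> tuple[bool, list[str]]:
        """Return (truth, reasons); reasons describe every atom evaluated."""
        k = self.kind
        if k == "and":
            results = [a.evaluate(ctx) for a in self.args]
            return all(r[0] for r in results), [s for r in results for s in r[1]]
        if k == "or":
            results = [a.evaluate(ctx) for a in self.args]
            return any(r[0] for r in results), [s for r in results for s in r[1]]
        if k == "not":
            truth, reasons = self.args[0].evaluate(ctx)
            return not truth, reasons
        truth = self._evaluate_atom(ctx)
        return truth, [f"{self.describe()}: {'satisfied' if truth else 'violated'}"]

    def _evaluate_atom(self, ctx: EvalContext) -> bool:
        k = self.kind
        if k == "const":
            return bool(self.value)
        if k == "age_cmp":
            from dmpkit.eligibility import age_at
            age = age_at(ctx.dataset.patient.birth_date, ctx.as_of)
            return _OPS[self.op](age, self.years)
        if k == "has_condition":
            return ctx.dataset.has_condition_prefix(self.icd10_prefix, ctx.as_of)
        if k == "on_medication_class":
            return ctx.dataset.on_medication_class(self.tag, ctx.as_of)
        if k == "observation_cmp":
            if self.code in ctx.session_values:
                return _OPS[self.op](ctx.session_values[self.code], self.threshold)
            concept = codes.by_code(self.code)
            found = latest_observation(ctx.dataset, concept, ctx.as_of,
                                       self.validity_months)
            if found.observation is None or found.freshness == Freshness.expired:
                return False
            return _OPS[self.op](found.observation.value, self.threshold)
        if k == "has_prior_encounter":
            cutoff = None
            if self.within_months is not None:
                cutoff = add_months(ctx.as_of, -self.within_months)
            for enc in ctx.dataset.encounters:
                if enc.module_id != self.module:
                    continue
                if enc.encounter_type != EncounterType(self.track):
                    continue
                if enc.date > ctx.as_of:
                    continue
                if cutoff is not None and enc.date < cutoff:
                    continue
                return True
            return False
        if k == "risk_category_is":
            return ctx.resolve_risk_category() == self.level
        raise AssertionError(f"unhandled atom kind {k}")

    def describe(self) -> str:
        k = self.kind
        if k == "const":
            return f"const({self.value})"
        if k == "age_cmp":
            return f"age {self.op} {self.years}"
        if k == "has_condition":
            return f"active condition {self.icd10_prefix}*"
        if k == "on_medication_class":
            return f"on {self.tag} medication"
        if k == "observation_cmp":
            return f"{self.code} {self.op} {self.threshold}"
        if k == "has_prior_encounter":
            win = f" within {self.within_months}m" if self.within_months else ""
            return f"prior {self.module}/{self.track} encounter{win}"
        if k == "risk_category_is":
            return f"risk category is {self.level}"
        return k


# -- convenience constructors ---------------------------------------------

def p_and(*args: PredicateExpr) -> PredicateExpr:
    return PredicateExpr(kind="and", args=list(args))


def p_or(*args: PredicateExpr) -> PredicateExpr:
    return PredicateExpr(kind="or", args=list(args))


def p_not(arg: PredicateExpr) -> PredicateExpr:
    return PredicateExpr(kind="not", args=[arg])


def p_const(value: bool) -> PredicateExpr:
    return PredicateExpr(kind="const", value=value)


def p_age(op: str, years: int) -> PredicateExpr:
    return PredicateExpr(kind="age_cmp", op=op, years=years)


def p_condition(icd10_prefix: str) -> PredicateExpr:
    return PredicateExpr(kind="has_condition", icd10_prefix=icd10_prefix)


def p_medication(tag: str) -> PredicateExpr:
    return PredicateExpr(kind="on_medication_class", tag=tag)


def p_obs(code: str, op: str, threshold: float,
          validity_months: Optional[int] = None) -> PredicateExpr:
    return PredicateExpr(kind="observation_cmp", code=code, op=op,
                         threshold=threshold, validity_months=validity_months)


def p_prior_encounter(module: str, track: str,
                      within_months: Optional[int] = None) -> PredicateExpr:
    return PredicateExpr(kind="has_prior_encounter", module=module,
                         track=track, within_months=within_months)


def p_risk(level: str) -> PredicateExpr:
    return PredicateExpr(kind="risk_category_is", level=level)
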