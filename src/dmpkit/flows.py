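"""Page-flow definitions and static flow validation.

A disease module's encounter is a wizard over pages, each corresponding
to one of the common care-pathway steps (physical examination, medical
history review, risk assessment, medication review, lab results review,
diagnosis, clinical goal setting, pharmacological and nonpharmacological
treatment planning, scaled assessment).  Transitions between pages are
guarded by predicates over the values entered so far; they are evaluated
in declaration order and the first match wins, so every page must end
with an unconditional catch-all transition.  Cycles are disallowed: a
valid flow is a DAG and therefore terminates within (number of pages)
steps.
"""

from __future__ import annotations

from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field

from dmpkit import codes
from dmpkit.predicates import PredicateExpr

TERMINAL = "TERMINAL"


class StepKind(str, Enum):
    physical_examination = "physical_examination"
    medical_history = "medical_history"
    risk_assessment = "risk_assessment"
    medication_review = "medication_review"
    lab_review = "lab_review"
    diagnosis = "diagnosis"
    goal_setting = "goal_setting"
    pharmacological_plan = "pharmacological_plan"
    nonpharmacological_plan = "nonpharmacological_plan"
    scaled_assessment = "scaled_assessment"


class RequiredParameter(BaseModel):
    code: str
    validity_months: Optional[int] = None
    prefill: bool = True
    optional: bool = False


class PageDefinition(BaseModel):
    page_id: str
    step_kind: StepKind
    required_parameters: list[RequiredParameter] = Field(default_factory=list)
    attached_cds_rules: list[str] = Field(default_factory=list)


class Transition(BaseModel):
    from_page: str
    predicate: Optional[PredicateExpr] = None  # None = unconditional
    to_page: str  # page_id or TERMINAL


class PageFlow(BaseModel):
    flow_id: str
    entry_page: str
    pages: list[PageDefinition]
    transitions: list[Transition]

    def page(self, page_id: str) -> PageDefinition:
        for p in self.pages:
            if p.page_id == page_id:
                return p
        raise KeyError(f"no page {page_id!r} in flow {self.flow_id!r}")

    def transitions_from(self, page_id: str) -> list[Transition]:
        return [t for t in self.transitions if t.from_page == page_id]


class FlowValidationReport(BaseModel):
    flow_id: str
    unreachable_pages: list[str] = Field(default_factory=list)
    nonterminating_pages: list[str] = Field(default_factory=list)
    undeclared_parameters: list[str] = Field(default_factory=list)
    other_problems: list[str] = Field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not (self.unreachable_pages or self.nonterminating_pages
                    or self.undeclared_parameters or self.other_problems)

    def problems(self) -> list[str]:
        out = [f"unreachable page {p}" for p in self.unreachable_pages]
        out += [f"non-terminating page {p}" for p in self.nonterminating_pages]
        out += [f"undeclared parameter {p}" for p in self.undeclared_parameters]
        out += self.other_problems
        return out


def _predicate_codes(expr: PredicateExpr) -> set[str]:
    found = set()
    if expr.kind == "observation_cmp" and expr.code:
        found.add(expr.code)
    for arg in expr.args:
        found |= _predicate_codes(arg)
    return found


def validate_flow(flow: PageFlow) -> FlowValidationReport:
    """Statically check reachability, termination, and parameter scoping.

    - every page must be reachable from the entry page;
    - the transition graph must be acyclic and every page's transition
      list must end in an unconditional transition (first-match semantics
      would otherwise strand a session);
    - transition predicates may only compare parameters declared on the
      originating page or on some earlier page of the flow (prefillable
      stored observations are also allowed, so this is a warning only for
      codes that no page declares at all).
    """
    report = FlowValidationReport(flow_id=flow.flow_id)
    page_ids = [p.page_id for p in flow.pages]
    if len(set(page_ids)) != len(page_ids):
        report.other_problems.append("duplicate page ids")
    if flow.entry_page not in page_ids:
        report.other_problems.append(f"entry page {flow.entry_page!r} undefined")
        return report

    for t in flow.transitions:
        if t.from_page not in page_ids:
            report.other_problems.append(
                f"transition from undefined page {t.from_page!r}")
        if t.to_page != TERMINAL and t.to_page not in page_ids:
            report.other_problems.append(
                f"transition to undefined page {t.to_page!r}")
    if report.other_problems:
        return report

    # reachability (BFS over transition edges)
    reachable = {flow.entry_page}
    frontier = [flow.entry_page]
    while frontier:
        page = frontier.pop()
        for t in flow.transitions_from(page):
            if t.to_page != TERMINAL and t.to_page not in reachable:
                reachable.add(t.to_page)
                frontier.append(t.to_page)
    report.unreachable_pages = sorted(set(page_ids) - reachable)

    # termination: acyclicity + a final catch-all on every reachable page
    for page in sorted(reachable):
        outs = flow.transitions_from(page)
        if not outs or outs[-1].predicate is not None:
            report.nonterminating_pages.append(page)
    # cycle detection by DFS colouring
    state: dict[str, int] = {}  # 0 visiting, 1 done

    def visit(page: str) -> bool:
        if state.get(page) == 0:
            return True  # back edge: cycle
        if state.get(page) == 1:
            return False
        state[page] = 0
        cyclic = False
        for t in flow.transitions_from(page):
            if t.to_page != TERMINAL and visit(t.to_page):
                cyclic = True
                if page not in report.nonterminating_pages:
                    report.nonterminating_pages.append(page)
        state[page] = 1
        return cyclic

    visit(flow.entry_page)
    report.nonterminating_pages = sorted(set(report.nonterminating_pages))

    # predicate parameter scoping
    declared = {rp.code for p in flow.pages for rp in p.required_parameters}
    for t in flow.transitions:
        if t.predicate is None:
            continue
        for code in sorted(_predicate_codes(t.predicate)):
            try:
                codes.by_code(code)
            except KeyError:
                report.undeclared_parameters.append(code)
                continue
            if code not in declared:
                report.undeclared_parameters.append(code)
    report.undeclared_parameters = sorted(set(report.undeclared_parameters))
    return report
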