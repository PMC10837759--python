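"""Eligibility evaluation, recall scheduling, and target-population lists.

A citizen is routed to at most one track per disease module: monitoring
takes precedence over screening (a diagnosed patient is never re-screened
for the same disease).  Recall due dates are the date of the last
completed encounter of that module/track plus the applicable interval;
with no prior encounter the patient is due immediately.  A patient is
``due_now`` on the due date itself and ``overdue`` strictly after it.
"""

from __future__ import annotations

import datetime as dt
from enum import Enum
from typing import Iterable, Optional

from pydantic import BaseModel

from dmpkit.model import EncounterType, PatientDataSet, add_months
from dmpkit.predicates import EvalContext
from dmpkit.registry import DiseaseModuleDefinition, ModuleRegistry


class Track(str, Enum):
    screening = "screening"
    monitoring = "monitoring"
    none = "none"


class Status(str, Enum):
    due_now = "due_now"
    overdue = "overdue"
    up_to_date = "up_to_date"
    not_eligible = "not_eligible"


class EligibilityDecision(BaseModel):
    module_id: str
    track: Track
    reasons: list[str]


class ScheduleStatus(BaseModel):
    module_id: str
    track: Track
    due_date: Optional[dt.date] = None
    status: Status


def age_at(birth_date: dt.date, as_of: dt.date) -> int:
    """Completed years of age; the age increments on the birthday itself.

    A Feb-29 birthday is completed on Mar 1 in non-leap years (the person
    has then lived the full year).
    """
    if birth_date > as_of:
        raise ValueError("birth_date is after as_of")
    years = as_of.year - birth_date.year
    anniversary = add_months(birth_date, 12 * years)
    if anniversary > as_of:
        years -= 1
    return years


def evaluate_eligibility(
    dataset: PatientDataSet,
    module: DiseaseModuleDefinition,
    as_of: dt.date,
    risk_category: Optional[str] = None,
) -> EligibilityDecision:
    """Decide the patient's track for one module at a date.

    Monitoring is checked first and wins when both predicates hold.
    The decision's reasons list every atom evaluated on the deciding
    predicate (plus the screening atoms when neither track applies).
    """
    ctx = EvalContext(dataset=dataset, as_of=as_of, risk_category=risk_category)
    mon, mon_reasons = module.monitoring_eligibility.evaluate(ctx)
    if mon:
        return EligibilityDecision(module_id=module.module_id,
                                   track=Track.monitoring, reasons=mon_reasons)
    scr, scr_reasons = module.screening_eligibility.evaluate(ctx)
    if scr:
        return EligibilityDecision(module_id=module.module_id,
                                   track=Track.screening, reasons=scr_reasons)
    return EligibilityDecision(module_id=module.module_id, track=Track.none,
                               reasons=mon_reasons + scr_reasons)


def _last_encounter_date(dataset: PatientDataSet, module_id: str,
                         track: Track, as_of: dt.date) -> Optional[dt.date]:
    dates = [e.date for e in dataset.encounters
             if e.module_id == module_id
             and e.encounter_type == EncounterType(track.value)
             and e.date <= as_of]
    return max(dates) if dates else None


def next_due(
    dataset: PatientDataSet,
    module: DiseaseModuleDefinition,
    as_of: dt.date,
    risk_category: Optional[str] = None,
) -> ScheduleStatus:
    """Recall status for one module at a date.

    The interval context key is the patient's risk category when the
    module's interval rule distinguishes risk levels (falling back to
    ``default`` when the risk is unknown).
    """
    decision = evaluate_eligibility(dataset, module, as_of, risk_category)
    if decision.track == Track.none:
        return ScheduleStatus(module_id=module.module_id, track=Track.none,
                              status=Status.not_eligible)
    last = _last_encounter_date(dataset, module.module_id, decision.track, as_of)
    if last is None:
        return ScheduleStatus(module_id=module.module_id, track=decision.track,
                              due_date=as_of, status=Status.due_now)
    ctx = EvalContext(dataset=dataset, as_of=as_of, risk_category=risk_category)
    context_key = ctx.resolve_risk_category()
    interval = module.interval_rule(decision.track.value).interval_for(context_key)
    due = add_months(last, interval)
    if due < as_of:
        status = Status.overdue
    elif due == as_of:
        status = Status.due_now
    else:
        status = Status.up_to_date
    return ScheduleStatus(module_id=module.module_id, track=decision.track,
                          due_date=due, status=status)


_STATUS_ORDER = {Status.overdue: 0, Status.due_now: 1, Status.up_to_date: 2}


def build_target_lists(
    population: Iterable[PatientDataSet],
    registry: ModuleRegistry,
    as_of: dt.date,
) -> dict[tuple[str, str], list[tuple[str, ScheduleStatus]]]:
    """Per-(module, track) target lists over a population.

    Each patient appears in at most one track per module.  Lists are
    sorted overdue-first, then by ascending due date, then by patient id
    for determinism.
    """
    lists: dict[tuple[str, str], list[tuple[str, ScheduleStatus]]] = {}
    for module_id in registry.modules:
        for track in (Track.screening, Track.monitoring):
            lists[(module_id, track.value)] = []
    for dataset in population:
        for module_id, module in registry.modules.items():
            schedule = next_due(dataset, module, as_of)
            if schedule.track == Track.none:
                continue
            lists[(module_id, schedule.track.value)].append(
                (dataset.patient_id, schedule))
    for key in lists:
        lists[key].sort(key=lambda item: (
            _STATUS_ORDER[item[1].status],
            item[1].due_date or dt.date.min,
            item[0],
        ))
    return lists
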