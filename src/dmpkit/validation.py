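"""Structural validators for the external JSON contracts.

Hand-written checks of the FHIR R4 CarePlan resource shape and of the
CDS Hooks discovery/request/card documents, covering required elements,
value-set bindings, reference resolution, and date syntax.  Each
validator returns a list of problem strings; empty means valid.
"""

from __future__ import annotations

import datetime as dt
from typing import Any

_CAREPLAN_STATUS = {"draft", "active", "on-hold", "revoked", "completed",
                    "entered-in-error", "unknown"}
_CAREPLAN_INTENT = {"proposal", "plan", "order", "option"}
_ACTIVITY_STATUS = {"not-started", "scheduled", "in-progress", "on-hold",
                    "completed", "cancelled", "stopped", "unknown",
                    "entered-in-error"}
_GOAL_LIFECYCLE = {"proposed", "planned", "accepted", "active", "on-hold",
                   "completed", "cancelled", "entered-in-error", "rejected"}
_CARD_INDICATORS = {"info", "warning", "critical"}


def _is_date(value: Any) -> bool:
    if not isinstance(value, str):
        return False
    try:
        dt.date.fromisoformat(value[:10])
        return True
    except ValueError:
        return False


def _check_reference(value: Any, path: str, problems: list[str]) -> None:
    if not isinstance(value, dict) or "reference" not in value:
        problems.append(f"{path}: missing reference")


def validate_care_plan(doc: dict) -> list[str]:
    """Structural validation of a FHIR R4 CarePlan JSON document."""
    problems: list[str] = []
    if doc.get("resourceType") != "CarePlan":
        problems.append("resourceType must be 'CarePlan'")
        return problems
    if doc.get("status") not in _CAREPLAN_STATUS:
        problems.append(f"status {doc.get('status')!r} not in R4 value set")
    if doc.get("intent") not in _CAREPLAN_INTENT:
        problems.append(f"intent {doc.get('intent')!r} not in R4 value set")
    _check_reference(doc.get("subject"), "subject", problems)

    contained_ids = set()
    for i, res in enumerate(doc.get("contained", [])):
        if "resourceType" not in res:
            problems.append(f"contained[{i}]: missing resourceType")
        if "id" not in res:
            problems.append(f"contained[{i}]: contained resources need an id")
        else:
            contained_ids.add(res["id"])
        if res.get("resourceType") == "Goal":
            if res.get("lifecycleStatus") not in _GOAL_LIFECYCLE:
                problems.append(f"contained[{i}]: invalid Goal.lifecycleStatus")
            if "description" not in res:
                problems.append(f"contained[{i}]: Goal.description is required")

    for i, ref in enumerate(doc.get("goal", [])):
        target = ref.get("reference", "")
        if target.startswith("#") and target[1:] not in contained_ids:
            problems.append(f"goal[{i}]: unresolved contained reference {target}")

    activities = doc.get("activity", [])
    if not isinstance(activities, list):
        problems.append("activity must be a list")
        activities = []
    for i, act in enumerate(activities):
        if "detail" not in act and "reference" not in act:
            problems.append(f"activity[{i}]: needs detail or reference")
            continue
        detail = act.get("detail", {})
        if detail:
            if detail.get("status") not in _ACTIVITY_STATUS:
                problems.append(
                    f"activity[{i}].detail.status {detail.get('status')!r} "
                    f"not in R4 value set")
            period = detail.get("scheduledPeriod", {})
            for bound in ("start", "end"):
                if bound in period and not _is_date(period[bound]):
                    problems.append(
                        f"activity[{i}].detail.scheduledPeriod.{bound}: "
                        f"not an ISO date")
    return problems


def validate_bundle(doc: dict) -> list[str]:
    problems: list[str] = []
    if doc.get("resourceType") != "Bundle":
        problems.append("resourceType must be 'Bundle'")
        return problems
    if doc.get("type") not in {"document", "message", "transaction",
                               "transaction-response", "batch",
                               "batch-response", "history", "searchset",
                               "collection"}:
        problems.append(f"Bundle.type {doc.get('type')!r} invalid")
    for i, entry in enumerate(doc.get("entry", [])):
        res = entry.get("resource")
        if not isinstance(res, dict) or "resourceType" not in res:
            problems.append(f"entry[{i}]: missing resource.resourceType")
    return problems


def validate_hooks_card(card: dict) -> list[str]:
    """Structural validation of one CDS Hooks response card."""
    problems: list[str] = []
    summary = card.get("summary")
    if not isinstance(summary, str) or not summary:
        problems.append("card.summary is required")
    elif len(summary) > 140:
        problems.append("card.summary must be at most 140 characters")
    if card.get("indicator") not in _CARD_INDICATORS:
        problems.append(f"card.indicator {card.get('indicator')!r} invalid")
    source = card.get("source")
    if not isinstance(source, dict) or not source.get("label"):
        problems.append("card.source.label is required")
    for i, sug in enumerate(card.get("suggestions", [])):
        if not sug.get("label"):
            problems.append(f"card.suggestions[{i}].label is required")
    return problems


def validate_hooks_response(doc: dict) -> list[str]:
    problems: list[str] = []
    cards = doc.get("cards")
    if not isinstance(cards, list):
        return ["response must carry a 'cards' list"]
    for i, card in enumerate(cards):
        problems += [f"cards[{i}]: {p}" for p in validate_hooks_card(card)]
    return problems


def validate_hooks_request(doc: dict) -> list[str]:
    problems: list[str] = []
    if not doc.get("hook"):
        problems.append("request.hook is required")
    if not doc.get("hookInstance"):
        problems.append("request.hookInstance is required")
    context = doc.get("context")
    if not isinstance(context, dict):
        problems.append("request.context is required")
    elif not context.get("patientId"):
        problems.append("request.context.patientId is required")
    prefetch = doc.get("prefetch", {})
    if prefetch and not isinstance(prefetch, dict):
        problems.append("request.prefetch must be an object")
    return problems


def validate_discovery(doc: dict) -> list[str]:
    problems: list[str] = []
    services = doc.get("services")
    if not isinstance(services, list):
        return ["discovery document must carry a 'services' list"]
    seen = set()
    for i, svc in enumerate(services):
        for field in ("id", "hook", "description"):
            if not svc.get(field):
                problems.append(f"services[{i}].{field} is required")
        if svc.get("id") in seen:
            problems.append(f"services[{i}]: duplicate id {svc.get('id')!r}")
        seen.add(svc.get("id"))
    return problems
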