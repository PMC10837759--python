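"""Population-level coverage, achievement, and goal statistics.

Aggregates encounter logs, target-population lists, and treatment goals
into the tables a national screening programme reports: coverage rate
(unique patients with at least one encounter of a track over its target
population), monthly achievement rate (encounters performed over the
monthly target), per-module encounter shares, mean encounters per
patient, and per-parameter goal achievement among re-assessed goals.

All percentages are rounded half-up to 1 decimal (2 decimals for the
per-patient mean), which reproduces printed programme tables exactly
from their printed counts.  A zero denominator is an undefined rate and
is reported as absent (None), never as 0.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel

from dmpkit.model import EncounterType, PatientDataSet
from dmpkit.registry import ModuleRegistry

# An FMP panel larger than this is exempt from programme use.
PANEL_EXEMPTION_THRESHOLD = 4000


class EncounterEvent(BaseModel):
    """One row of an encounter log."""

    patient_id: str
    module_id: str
    track: EncounterType
    date: dt.date
    performer: str = ""


def round_half_up(value: float, decimals: int) -> float:
    exp = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(exp, rounding=ROUND_HALF_UP))


def percent(numerator: int, denominator: int,
            decimals: int = 1) -> Optional[float]:
    """100 * numerator / denominator, rounded half-up.

    Exact decimal arithmetic: printed programme percentages are
    reproduced from their printed counts without binary-float artefacts.
    A zero denominator returns None (undefined, rendered as absent).
    """
    if denominator == 0:
        return None
    exp = Decimal(1).scaleb(-decimals)
    raw = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(raw.quantize(exp, rounding=ROUND_HALF_UP))


TargetLists = Mapping[tuple[str, str], Sequence]


def _target_patient_ids(entries: Sequence) -> set[str]:
    ids = set()
    for entry in entries:
        if isinstance(entry, str):
            ids.add(entry)
        else:  # (patient_id, ScheduleStatus) pairs from build_target_lists
            ids.add(entry[0])
    return ids


def coverage(target_lists: TargetLists,
             encounter_log: Iterable[EncounterEvent]) -> pd.DataFrame:
    """Coverage per (module, track): unique patients with >= 1 encounter.

    A patient with several encounters of a track counts once; a patient
    present in both tracks over time counts in each track separately.
    """
    covered: dict[tuple[str, str], set[str]] = {}
    for event in encounter_log:
        covered.setdefault((event.module_id, event.track.value),
                           set()).add(event.patient_id)
    rows = []
    for (module_id, track), entries in sorted(target_lists.items()):
        targets = _target_patient_ids(entries)
        covered_ids = covered.get((module_id, track), set())
        n_covered = len(covered_ids & targets) if targets else len(covered_ids)
        rows.append({
            "module": module_id,
            "track": track,
            "target_count": len(targets),
            "covered_count": n_covered,
            "coverage_percent": percent(n_covered, len(targets)),
        })
    return pd.DataFrame(rows, columns=["module", "track", "target_count",
                                       "covered_count", "coverage_percent"])


def achievement(
    monthly_targets: Mapping[tuple[str, str], int],
    encounter_log: Iterable[EncounterEvent],
    month: Union[str, tuple[int, int]],
) -> tuple[pd.DataFrame, Optional[float]]:
    """Monthly achievement per (module, track), plus the overall rate.

    The overall rate is computed from summed counts (total performed over
    total target), never by averaging the per-module percentages.
    """
    if isinstance(month, str):
        year, mon = (int(p) for p in month.split("-")[:2])
    else:
        year, mon = month
    performed: dict[tuple[str, str], int] = {}
    for event in encounter_log:
        if event.date.year == year and event.date.month == mon:
            key = (event.module_id, event.track.value)
            performed[key] = performed.get(key, 0) + 1
    rows = []
    total_target = total_performed = 0
    for (module_id, track), target in sorted(monthly_targets.items()):
        done = performed.get((module_id, track), 0)
        total_target += target
        total_performed += done
        rows.append({
            "module": module_id,
            "track": track,
            "monthly_target": target,
            "performed": done,
            "achievement_percent": percent(done, target),
        })
    table = pd.DataFrame(rows, columns=["module", "track", "monthly_target",
                                        "performed", "achievement_percent"])
    return table, percent(total_performed, total_target)


@dataclass
class EncounterSummary:
    per_module: pd.DataFrame
    total_encounters: int
    unique_patients: int
    mean_encounters_per_patient: Optional[float]
    sex_shares: dict[str, Optional[float]] = field(default_factory=dict)


def encounter_summary(
    encounter_log: Sequence[EncounterEvent],
    patient_sex: Optional[Mapping[str, str]] = None,
) -> EncounterSummary:
    """Per-module encounter counts, screening/monitoring split, module
    shares of the grand total, and the mean encounters per unique patient
    (half-up, 2 decimals)."""
    events = list(encounter_log)
    counts: dict[str, dict[str, int]] = {}
    patients: set[str] = set()
    for event in events:
        mod = counts.setdefault(event.module_id,
                                {"screening": 0, "monitoring": 0})
        mod[event.track.value] += 1
        patients.add(event.patient_id)
    grand_total = len(events)
    rows = []
    for module_id in sorted(counts):
        screening = counts[module_id]["screening"]
        monitoring = counts[module_id]["monitoring"]
        total = screening + monitoring
        rows.append({
            "module": module_id,
            "screening": screening,
            "monitoring": monitoring,
            "total": total,
            "share_percent": percent(total, grand_total),
        })
    per_module = pd.DataFrame(rows, columns=["module", "screening",
                                             "monitoring", "total",
                                             "share_percent"])
    mean = None
    if patients:
        mean = round_half_up(grand_total / len(patients), 2)
    sex_shares: dict[str, Optional[float]] = {}
    if patient_sex and patients:
        by_sex: dict[str, int] = {}
        for pid in patients:
            sex = patient_sex.get(pid)
            if sex:
                by_sex[sex] = by_sex.get(sex, 0) + 1
        for sex, n in sorted(by_sex.items()):
            sex_shares[sex] = percent(n, len(patients))
    return EncounterSummary(
        per_module=per_module,
        total_encounters=grand_total,
        unique_patients=len(patients),
        mean_encounters_per_patient=mean,
        sex_shares=sex_shares,
    )


def goal_achievement(
    datasets: Iterable[PatientDataSet],
    as_of: dt.date,
) -> pd.DataFrame:
    """Per-parameter goal achievement among assessed goals.

    A goal counts as *assessed* when an observation of its parameter
    exists strictly after the goal's set date and at or before `as_of`
    (a later encounter re-measured it); it is *achieved* when the latest
    such observation satisfies the goal's comparator against its target.
    Goals never re-assessed are excluded from the denominator.
    """
    assessed: dict[str, int] = {}
    achieved: dict[str, int] = {}
    display: dict[str, str] = {}
    for dataset in datasets:
        for goal in dataset.goals:
            later = [o for o in dataset.observations
                     if o.code.key() == goal.parameter.key()
                     and goal.set_date < o.effective_date <= as_of]
            if not later:
                continue
            code = goal.parameter.code
            display[code] = goal.parameter.display or code
            assessed[code] = assessed.get(code, 0) + 1
            latest = max(later, key=lambda o: o.effective_date)
            if goal.satisfied_by(latest.value):
                achieved[code] = achieved.get(code, 0) + 1
    rows = []
    for code in sorted(assessed):
        rows.append({
            "parameter": code,
            "display": display[code],
            "assessed_count": assessed[code],
            "achieved_count": achieved.get(code, 0),
            "achievement_percent": percent(achieved.get(code, 0),
                                           assessed[code]),
        })
    return pd.DataFrame(rows, columns=["parameter", "display",
                                       "assessed_count", "achieved_count",
                                       "achievement_percent"])


@dataclass
class PanelView:
    fmp_id: str
    panel_size: int
    exempt: bool
    target_lists: dict
    notice: str = ""


def panel_view(
    fmp_id: str,
    population: Iterable[PatientDataSet],
    registry: ModuleRegistry,
    as_of: dt.date,
) -> PanelView:
    """One practitioner's due/overdue lists with the panel-size exemption.

    The lists equal the global target lists restricted to the panel.
    A panel strictly larger than 4000 citizens sets the exempt flag.
    """
    from dmpkit.eligibility import build_target_lists

    panel = [ds for ds in population if ds.patient.assigned_fmp == fmp_id]
    if not panel:
        return PanelView(fmp_id=fmp_id, panel_size=0, exempt=False,
                         target_lists={},
                         notice=f"no patients assigned to {fmp_id!r}")
    lists = build_target_lists(panel, registry, as_of)
    return PanelView(
        fmp_id=fmp_id,
        panel_size=len(panel),
        exempt=len(panel) > PANEL_EXEMPTION_THRESHOLD,
        target_lists=lists,
    )


@dataclass
class PopulationStats:
    """Bundle of every aggregate table for one reporting run."""

    coverage: pd.DataFrame
    achievement: pd.DataFrame
    overall_achievement_percent: Optional[float]
    summary: EncounterSummary
    goal_table: pd.DataFrame
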