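"""Population statistics: exact percentages, coverage, achievement, goals."""

import datetime as dt
import random

import pandas as pd
import pytest

from dmpkit import codes
from dmpkit.eligibility import build_target_lists
from dmpkit.model import Comparator, GoalRecord
from dmpkit.population import (
    PANEL_EXEMPTION_THRESHOLD,
    EncounterEvent,
    achievement,
    coverage,
    encounter_summary,
    goal_achievement,
    panel_view,
    percent,
    round_half_up,
)
from dmpkit.synthetic import CohortConfig, generate_encounter_log, \
    generate_population

from conftest import AS_OF, make_patient, observation


# ---------------------------------------------------------------------------
# exact decimal percentages

@pytest.mark.parametrize("num,den,expected", [
    (10_820_774, 48_443_467, 22.3),   # national-scale counts reproduce
    (4_508_841, 19_546_041, 23.1),    # their printed one-decimal rates
    (670_502, 898_665, 74.6),
    (1, 3, 33.3),
    (2, 3, 66.7),
    (125, 10_000, 1.3),               # 1.25 rounds half-UP, not to even
    (135, 10_000, 1.4),
    (0, 5, 0.0),
    (5, 5, 100.0),
])
def test_percent_reproduces_printed_rates(num, den, expected):
    assert percent(num, den) == expected


def test_zero_denominator_is_absent_not_zero():
    assert percent(0, 0) is None
    assert percent(7, 0) is None


def test_mean_uses_two_decimals_half_up():
    assert round_half_up(73_715_269 / 16_058_904, 2) == 4.59
    assert round_half_up(2.005, 2) == 2.01
    assert round_half_up(2.004, 2) == 2.0


# ---------------------------------------------------------------------------
# coverage

def _ev(pid, module="hypertension", track="screening", date=AS_OF):
    return EncounterEvent(patient_id=pid, module_id=module, track=track,
                          date=date)


def test_coverage_counts_unique_patients_once():
    targets = {("hypertension", "screening"): ["a", "b", "c", "d"]}
    log = [_ev("a"), _ev("a"), _ev("b"), _ev("zz")]  # zz not in target
    table = coverage(targets, log)
    row = table.iloc[0]
    assert row["target_count"] == 4
    assert row["covered_count"] == 2
    assert row["coverage_percent"] == 50.0


def test_coverage_empty_target_list_has_absent_rate():
    table = coverage({("diabetes", "screening"): []}, [])
    assert table.iloc[0]["coverage_percent"] is None


def test_coverage_matches_set_arithmetic_brute_force(registry):
    population = generate_population(CohortConfig(n=200, seed=21))
    lists = build_target_lists(population, registry, AS_OF)
    targets = {key: [pid for pid, _ in entries]
               for key, entries in lists.items()}
    events, _ = generate_encounter_log(
        population, 3, CohortConfig(n=200, seed=21, adherence=0.6), registry)
    table = coverage(targets, events)
    for _, row in table.iterrows():
        key = (row["module"], row["track"])
        expected = len({e.patient_id for e in events
                        if (e.module_id, e.track.value) == key}
                       & set(targets[key]))
        assert row["covered_count"] == expected
        want = percent(expected, len(targets[key]))
        if want is None:  # absent rate surfaces as NaN in the float column
            assert pd.isna(row["coverage_percent"])
        else:
            assert row["coverage_percent"] == want


# ---------------------------------------------------------------------------
# achievement

def test_achievement_counts_only_the_requested_month():
    targets = {("hypertension", "monitoring"): 10,
               ("diabetes", "screening"): 5}
    log = [_ev("a", "hypertension", "monitoring", dt.date(2023, 6, 10)),
           _ev("b", "hypertension", "monitoring", dt.date(2023, 6, 20)),
           _ev("c", "hypertension", "monitoring", dt.date(2023, 7, 1)),
           _ev("d", "diabetes", "screening", dt.date(2023, 6, 5))]
    table, overall = achievement(targets, log, "2023-06")
    by_key = {(r["module"], r["track"]): r for _, r in table.iterrows()}
    assert by_key[("hypertension", "monitoring")]["performed"] == 2
    assert by_key[("hypertension", "monitoring")]["achievement_percent"] == 20.0
    assert by_key[("diabetes", "screening")]["achievement_percent"] == 20.0
    assert overall == percent(3, 15)  # summed counts, 20.0


def test_overall_achievement_is_not_a_mean_of_percentages():
    # 9/10 and 1/90: mean of percents would be 45.6; count-based is 10.0
    targets = {("a", "screening"): 10, ("b", "screening"): 90}
    log = ([_ev(f"p{i}", "a", "screening", dt.date(2023, 6, 1))
            for i in range(9)]
           + [_ev("q", "b", "screening", dt.date(2023, 6, 1))])
    _, overall = achievement(targets, log, (2023, 6))
    assert overall == 10.0


def test_achievement_recombination_identity(registry):
    """Overall rate recomputed from the table's own columns agrees."""
    population = generate_population(CohortConfig(n=300, seed=22))
    events, monthly = generate_encounter_log(
        population, 2, CohortConfig(n=300, seed=22, adherence=0.8), registry)
    for month, targets in monthly.items():
        table, overall = achievement(targets, events, month)
        assert overall == percent(int(table["performed"].sum()),
                                  int(table["monthly_target"].sum()))


# ---------------------------------------------------------------------------
# encounter summary

def test_encounter_summary_totals_shares_and_mean():
    log = [_ev("a", "hypertension", "monitoring"),
           _ev("a", "hypertension", "monitoring"),
           _ev("a", "diabetes", "screening"),
           _ev("b", "diabetes", "screening")]
    summary = encounter_summary(log, patient_sex={"a": "female", "b": "male"})
    assert summary.total_encounters == 4
    assert summary.unique_patients == 2
    assert summary.mean_encounters_per_patient == 2.0
    by_module = summary.per_module.set_index("module")
    assert by_module.loc["hypertension", "monitoring"] == 2
    assert by_module.loc["hypertension", "share_percent"] == 50.0
    assert by_module.loc["diabetes", "share_percent"] == 50.0
    assert summary.sex_shares == {"female": 50.0, "male": 50.0}


def test_encounter_summary_empty_log():
    summary = encounter_summary([])
    assert summary.total_encounters == 0
    assert summary.mean_encounters_per_patient is None
    assert len(summary.per_module) == 0


def test_shares_computed_from_counts_match_percent_oracle():
    rng = random.Random(5)
    modules = ["hypertension", "diabetes", "obesity"]
    log = [_ev(f"p{rng.randrange(40)}", rng.choice(modules),
               rng.choice(["screening", "monitoring"]))
           for _ in range(500)]
    summary = encounter_summary(log)
    for _, row in summary.per_module.iterrows():
        assert row["share_percent"] == percent(int(row["total"]), 500)


# ---------------------------------------------------------------------------
# goal achievement

def _goal(target=140.0, set_date=dt.date(2023, 1, 1)):
    return GoalRecord(parameter=codes.SBP, comparator=Comparator.le,
                      target_value=target, unit="mmHg", set_date=set_date)


def test_goal_achievement_assessed_and_achieved():
    achieved = make_patient(patient_id="a", observations=[
        observation(codes.SBP, 135, dt.date(2023, 3, 1))])
    achieved.goals.append(_goal())
    missed = make_patient(patient_id="b", observations=[
        observation(codes.SBP, 150, dt.date(2023, 3, 1))])
    missed.goals.append(_goal())
    table = goal_achievement([achieved, missed], AS_OF)
    row = table.iloc[0]
    assert row["assessed_count"] == 2
    assert row["achieved_count"] == 1
    assert row["achievement_percent"] == 50.0


def test_goal_never_reassessed_is_excluded():
    # only a measurement from BEFORE the goal was set
    ds = make_patient(observations=[
        observation(codes.SBP, 135, dt.date(2022, 12, 1))])
    ds.goals.append(_goal())
    assert len(goal_achievement([ds], AS_OF)) == 0


def test_goal_assessment_ignores_future_observations():
    ds = make_patient(observations=[
        observation(codes.SBP, 135, dt.date(2024, 1, 1))])
    ds.goals.append(_goal())
    assert len(goal_achievement([ds], AS_OF)) == 0


def test_goal_judged_on_latest_reassessment():
    ds = make_patient(observations=[
        observation(codes.SBP, 135, dt.date(2023, 2, 1)),
        observation(codes.SBP, 155, dt.date(2023, 4, 1)),  # latest: missed
    ])
    ds.goals.append(_goal())
    table = goal_achievement([ds], AS_OF)
    assert table.iloc[0]["achieved_count"] == 0


# ---------------------------------------------------------------------------
# panel view

def test_panel_exemption_strictly_above_4000(registry):
    big = [make_patient(patient_id=f"p{i}", fmp="fmp-big")
           for i in range(PANEL_EXEMPTION_THRESHOLD + 1)]
    view = panel_view("fmp-big", big, registry, AS_OF)
    assert view.panel_size == 4001 and view.exempt

    at_threshold = big[:PANEL_EXEMPTION_THRESHOLD]
    view = panel_view("fmp-big", at_threshold, registry, AS_OF)
    assert not view.exempt


def test_panel_view_restricts_global_lists(registry):
    population = generate_population(CohortConfig(n=120, seed=23))
    fmp_ids = {ds.patient.assigned_fmp for ds in population}
    global_lists = build_target_lists(population, registry, AS_OF)
    for fmp_id in sorted(fmp_ids):
        view = panel_view(fmp_id, population, registry, AS_OF)
        panel_ids = {ds.patient_id for ds in population
                     if ds.patient.assigned_fmp == fmp_id}
        for key, entries in view.target_lists.items():
            expected = [pid for pid, _ in global_lists[key]
                        if pid in panel_ids]
            assert sorted(pid for pid, _ in entries) == sorted(expected)
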