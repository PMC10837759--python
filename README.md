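# dmpkit

A toolkit for nationwide chronic-disease screening and monitoring
programmes in primary care. It models the machinery such a programme
needs end to end: longitudinal patient records exchanged as HL7 FHIR R4
bundles, declaratively configured disease modules (hypertension,
diabetes, cardiovascular risk, obesity, older-adult care), eligibility
and recall scheduling, guided encounter page flows, rule-driven clinical
decision support exposed over the CDS Hooks contract, population-level
coverage/achievement statistics, and a seeded synthetic cohort generator
for experimentation.

## The problem

A screening programme must answer, for every citizen and every disease
module, four questions:

1. **Eligibility** — which track applies right now? A citizen with an
   active diagnosis and ongoing treatment belongs to *monitoring*; an
   undiagnosed citizen matching the screening criteria belongs to
   *screening*; otherwise neither. Example rules shipped as defaults:
   diabetes screening requires age > 40 (strict) and no active E10–E14
   diagnosis; hypertension monitoring requires an active I10–I15
   diagnosis *and* ongoing antihypertensive medication.
2. **Recall** — when is the next encounter due? Each module/track has a
   calendar-month interval (diabetes screening every 36 months,
   hypertension monitoring every 3 months, cardiovascular-risk screening
   every 24 months at low risk and 12 months at high risk). A citizen is
   *due* on the due date and *overdue* strictly after it.
3. **The encounter itself** — a page-flow state machine that prefills
   still-valid measurements, requires expired ones to be re-taken,
   routes on entered values (e.g. SBP ≥ 140 or DBP ≥ 90 → confirmation
   page → diagnosis suggestion), runs the decision-support rules, and
   assembles a FHIR CarePlan with goals, referrals, and the follow-up
   appointment.
4. **Accountability** — coverage rate (unique patients seen over the
   target population), monthly achievement rate (encounters performed
   over the monthly target), and treatment-goal attainment, all with
   exact decimal arithmetic so printed percentages are reproducible from
   printed counts.

## Core model

Cardiovascular risk uses the SCORE functional form: for each cause
stratum (CHD / non-CHD) a Weibull baseline survival

```
S0(t) = exp(-exp(alpha) * (t - 20)^p)
```

is scaled by the linear predictor
`w = beta_smoker*smoker + beta_sbp*(SBP - 120) + beta_chol*(chol - 6)`
(cholesterol in mmol/L), giving `S(t) = S0(t)^exp(w)`. The 10-year fatal
risk conditional on surviving to age *a* is `1 - S(a+10)/S(a)`, summed
over the two strata and capped at 100%. The shipped coefficient table is
the published 2003 low-risk calibration, labelled *demonstration*;
national calibrations plug in as data. Risk categories: `< 1%` low,
`1–<5%` moderate, `5–<10%` high, `>= 10%` very high.

All eligibility criteria, intervals, flows, decision rules,
contraindications, and goal policies are configuration (`ModuleRegistry`),
validated structurally and replaceable via YAML without code changes.

## Worked example

```python
import datetime as dt
from dmpkit import (builtin_defaults, CohortConfig, generate_population,
                    build_target_lists, start_encounter, submit_page,
                    complete_encounter, TERMINAL)

registry = builtin_defaults()
population = generate_population(CohortConfig(n=100, seed=42))
as_of = dt.date(2023, 6, 1)

lists = build_target_lists(population, registry, as_of)
print({k: len(v) for k, v in lists.items() if v})
```

prints (deterministically, for seed 42):

```
{('hypertension', 'screening'): 74, ('hypertension', 'monitoring'): 21,
 ('diabetes', 'screening'): 68, ('diabetes', 'monitoring'): 10,
 ('cvd_risk', 'screening'): 77, ('obesity', 'screening'): 80,
 ('obesity', 'monitoring'): 14, ('older_adult', 'monitoring'): 16}
```

Running a screening encounter with an elevated blood pressure and a
raised fasting glucose:

```python
module = registry.module("hypertension")
patient = next(ds for ds in population if not ds.conditions)
session = start_encounter(patient, module, "screening", as_of,
                          registry=registry)
submit_page(session, {"8480-6": 152.0, "8462-4": 96.0})   # vitals
submit_page(session, {"8480-6": 149.0, "8462-4": 94.0})   # confirmation
while session.current_page != TERMINAL:
    page = session.flow.page(session.current_page)
    submit_page(session, {rp.code: 95.0 for rp in page.required_parameters
                          if rp.code not in session.effective_values()})
result = complete_encounter(session)
print([c.rule_id for c in session.emitted_cards])
print([(g.parameter.code, g.comparator.value, g.target_value)
       for g in result.care_plan.goals])
print([(a.kind.value, a.due_date) for a in result.care_plan.activities])
```

```
['htn-diagnosis', 'goal:hypertension:8480-6', 'goal:hypertension:8462-4',
 'follow-up:hypertension:screening']
[('8480-6', 'le', 140.0), ('8462-4', 'le', 90.0)]
[('follow_up_appointment', datetime.date(2024, 6, 1))]
```

The same rules are served over CDS Hooks (`dmp serve-cds`), and the CLI
covers the full pipeline:

```
dmp generate-population --n 1000 --seed 7 --out pop/
dmp target-lists --as-of 2023-06-01 --population pop/ --out targets.csv
dmp run-encounter --patient pop/p000003.json --module hypertension \
    --as-of 2023-06-01 --script visit.yaml
dmp stats --log encounters.csv --targets monthly.csv --month 2023-06 \
    --out stats.json
dmp validate-registry --dump registry.yaml
```

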