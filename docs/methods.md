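# Methods

This document describes the models, procedures, parameter defaults, and
numerical conventions implemented in `dmpkit`, and the design decisions
behind them.

## 1. Clinical data model and FHIR mapping

The internal unit of state is the `PatientDataSet`: one patient plus
their conditions, medications, observations, encounters, goals, and care
plans. Externally it is exchanged as a plain-JSON HL7 FHIR R4 `Bundle`
containing exactly one `Patient` plus `Condition`, `MedicationStatement`,
`Observation`, `Encounter`, `Goal`, and `CarePlan` resources.
Domain-specific attributes that have no natural FHIR element (encounter
module/track, observation origin, activity kind) travel in extensions
under the `urn:dmp:` namespace, so `read_bundle(write_bundle(x)) == x`
for all supported content; unsupported resource types are counted and
skipped, never fatal. Care plans are exported with their goals as
contained resources referenced `#goal-i`.

Incremental synchronization uses per-resource identity tuples (for an
observation: coding system, code, effective date, origin). `merge`
replaces same-identity entries with the delta's version (a delta is a
correction) and is idempotent and order-insensitive for disjoint deltas.
Merging data for a different patient id is an error.

### Calendar arithmetic

All intervals are calendar months with day clamping
(`dateutil.relativedelta`): Jan 31 + 1 month = Feb 28 (29 in leap
years). `whole_months_between(a, b)` is the largest k with
`a + k months <= b`; under clamping, Jan 31 → Feb 28 is therefore 1
completed month. Age increments on the birthday itself. These
conventions are applied uniformly to recall scheduling, observation
validity, and age thresholds.

### Observation validity

`latest_observation(dataset, code, as_of, validity_months)` returns the
newest observation not after `as_of` with a freshness flag: *fresh*
within the validity period, *expired* beyond it, *absent* when never
measured. On equal dates an in-encounter entry beats a synchronized
value. Every validity period is per-module configuration (defaults: BP
6 months, HbA1c 6, glucose/lipids/eGFR/BMI 12, height 60).

## 2. Disease modules as configuration

A `DiseaseModuleDefinition` declares, as data: screening and monitoring
eligibility predicates, recall interval rules, parameter validity
periods, the page flow, decision-support rule descriptors,
contraindications, goal policies, and the lab panel. Predicates are
expression trees (`and`/`or`/`not` over atoms: age comparison, ICD-10
prefix condition, medication class, observation comparison with
validity, prior encounter, risk category). The same predicate language
drives eligibility and flow transitions; in-session values take
precedence over stored observations.

Registry validation is structural and total: dangling flow references,
non-positive intervals, undeclared flow parameters, non-terminating or
unreachable pages, and malformed predicates are all collected and
reported together. The shipped defaults encode the programme rules:

| rule | value |
|---|---|
| diabetes screening | age > 40 (strict), no active E10–E14, recall 36 months |
| hypertension monitoring | active I10–I15 + ongoing antihypertensive, recall 3 months |
| cardiovascular-risk screening | recall 24 months (low risk) / 12 months (high or very high) |
| obesity monitoring | primary care only when not advanced obesity (BMI > 40, or BMI in (30, 40] with comorbidity) |
| FPG transition prompt | fasting glucose > 110 mg/dL (strict), patient not already diabetes-monitored |
| eGFR referral | fresh eGFR < 60 mL/min/1.73 m² (strict) → nephrology |
| retinopathy check | yearly ophthalmology referral during diabetes monitoring |
| panel exemption | practitioner panels > 4000 citizens are exempt |

Intervals not fixed by the rules above (hypertension screening 12
months, diabetes monitoring 3 months or 6 when controlled,
cardiovascular-risk monitoring 12, obesity screening 12 / monitoring 3,
older adult 12) are package configuration defaults, replaceable via
YAML.

## 3. Eligibility and scheduling

Monitoring takes precedence over screening: a citizen matching both is
listed once, under monitoring. `next_due` resolves the interval context
(the stored risk category for the cardiovascular module, control status
for diabetes monitoring), adds the interval to the last matching
encounter date, and classifies: *up to date* before the due date, *due*
on it, *overdue* strictly after; no prior encounter is due immediately.
Target lists sort overdue first, then by due date, then patient id, and
are disjoint across tracks within a module by construction.

## 4. Encounter page flows

A flow is a DAG of pages with first-match transitions; a final
catch-all transition per page is mandatory, and `validate_flow` proves
termination (no cycles, no dead ends) and reachability statically, so a
session can never strand. Starting an encounter re-checks eligibility
(violations are reported with the failing atoms) and prefills required
parameters from the record with freshness flags; expired values are
excluded from the effective values and must be re-entered. Submitted
values are unit-checked and schema-checked, recorded as
encounter-entry observations on a working copy, and trigger the page's
attached decision rules. Completion requires the terminal state,
assembles the CarePlan (accepted goal and referral cards plus the
mandatory follow-up appointment with its due date), updates the recall
schedule, and returns any cross-module transition prompts.

## 5. Decision-support rule families

Nine pure rule families (same inputs → identical cards): risk scoring,
diagnosis suggestion, lab-order guidance, lab-driven referral, goal
recommendation, medication advice with contraindication warnings,
preventive referral, follow-up scheduling, and module transition. Each
is exposed as one CDS Hooks service; the discovery document lists all
nine, and every response card carries the full library card in an
extension, byte-identical to a direct library call — the HTTP layer adds
transport only. An empty prefetch yields a data-request card, never an
error; schema violations map to 400, unknown services to 404.

### Cardiovascular risk score

SCORE functional form, per cause stratum (CHD and non-CHD):

- baseline survival `S0(t) = exp(-exp(alpha) * (t - 20)^p)` (Weibull),
- linear predictor `w = b_smoker*smoker + b_sbp*(SBP-120) + b_chol*(chol-6)`
  with cholesterol in mmol/L,
- `S(t) = S0(t)^exp(w)`, 10-year risk `1 - S(a+10)/S(a)`,
- total risk = CHD + non-CHD, capped at 100%.

Supported input ranges: age 30–90, SBP 70–260 mmHg, cholesterol
2–12 mmol/L; out-of-range inputs raise errors naming the bound. The
shipped coefficients are the published 2003 low-risk-region calibration
and are labelled *demonstration*: the national calibration used in
production programmes is not public, so only the functional form is
asserted, and coefficient tables are plain data. Categories: < 1% low,
1–< 5% moderate, 5–< 10% high, ≥ 10% very high (configurable
thresholds, lower bound inclusive).

## 6. Population statistics

All rates are computed with exact decimal arithmetic
(`decimal.Decimal`, rounding half-up, 1 decimal; 2 decimals for the
mean encounters per patient), so printed programme percentages are
reproduced exactly from printed counts. A zero denominator is an
undefined rate reported as absent (`None`/NaN), never 0. Coverage
counts unique patients with at least one encounter of a track over its
target population; achievement counts encounters performed in a month
over the monthly target; the overall achievement rate is computed from
summed counts, never by averaging percentages. Goal achievement counts
only goals re-assessed after they were set (an observation of the
parameter strictly after the set date and at or before the reporting
date) and judges the latest re-assessment against the goal comparator.

## 7. Synthetic cohort generator

`generate_population(CohortConfig)` is a pure function of its
configuration, including the seed (`numpy.random.default_rng`).
Defaults: age ~ Normal(50, 16) clipped to [18, 95] (birth dates are
constructed so the completed age at the index date is exactly the drawn
age); 56.2% female; age-banded prevalence (hypertension 5/20/40%,
diabetes 3/12/20% for ages 18–39/40–59/60+, obesity 20%); medication
given diagnosis 80%; smoking 25%; three yearly observation rounds drawn
from truncated normals conditioned on disease status, with correct
units. `generate_encounter_log` simulates monthly recall cycles driven
by the real eligibility engine: each month, every due patient enters the
target count and attends with the configured adherence probability,
appending the encounter so later months see the updated schedule.

The generator claims no real demography: it exists to exercise the
pipeline and to make statistical properties (prevalence recovery,
adherence limit cases, coverage arithmetic) testable. Rates, bands, and
noise models are all configuration.

## 8. Numerical and engineering choices

- Exact `Decimal` half-up for all reported rates; binary floats are
  never rounded for display.
- Deterministic JSON serialization (sorted keys) for byte-stability
  checks of bundles and cards.
- pydantic v2 models validate every external input; structural
  validators (bundle, care plan, hooks request/response/card,
  discovery) return complete problem lists rather than failing on the
  first issue.
- Sub-seeds derived in the acceptance script stay below 2^31.

## 9. Open decisions and limitations

- The risk coefficients are a demonstration calibration; national
  calibrations must be supplied as data before clinical use.
- Monitoring "control status" (controlled/uncontrolled) is accepted as
  an input to interval rules but no classifier is shipped to derive it.
- The HTTP layer is a single-threaded standard-library server intended
  for local use, not deployment.
- Flow transitions evaluate on session values only at submit time;
  mid-page reactive validation is out of scope.
- Non-goals inherited from the design: identity management, consent,
  real EHR connectivity, secondary/tertiary-care workflows.
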