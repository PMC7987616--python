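# Methods

`ehrcohort` automates the extraction of analysable datasets for
observational studies — cohort, case–control and cross-sectional — from
longitudinal primary-care-style EHR tables. This note records the model
behind each stage, the conventions and tunable parameters, what the
synthetic generator does and does not emulate, and the design choices made
where more than one reading was defensible.

## The extraction model

The pipeline is a staged ETL workflow over three relational source tables
(practice, patient, coded events). Each stage consumes the survivors of the
previous one; every patient removed anywhere is counted under a fixed
reason string in a per-stage rejection map. The central verifiability
guarantee is conservation: at every stage, input count − output count must
equal the stage's summed rejection counts, and overall, dataset rows plus
all rejections must equal the stage-1 input population. A violation is a
hard `AuditConsistencyError`, never a warning, and the CLI exits non-zero.

### Stage 1 — eligible period

Per practice: `start = max(key_date + key_date_offset_days, study_start)`,
`end = min(study_end, collection_date)`. The three data-quality key dates
(computerisation, acceptable mortality rate, healthcare system) are
pre-combined into one `key_date = latest of those provided` at load time —
they act as a unit and only their maximum matters downstream.

Per patient: `patient_start = max(registration + registration_leadin_days,
practice_start, date of attaining entry_age_min)`; `patient_end =
min(practice_end, deregistration, death, last day at age ≤ exit_age_max)`.
Checks run (and the first failure is recorded) in the order the stage's
rules are stated: entry-age ceiling, sex filter, practice-window overlap,
empty window. The overlap test is read literally as strict
(`patient_start < practice_end` and `patient_end > practice_start`) even
though every other interval in the package is closed; this is a deliberate
literal reading, fixed and tested.

Conventions: all intervals are closed unless stated; ages are completed
years; a Feb-29 birthday rolls to Mar-1 in non-leap years; year-precision
birth dates are anchored to July 1 (configurable to January 1) for age
arithmetic.

### Stage 2 — exposure and index date

Each inclusion code entity is located in the patient's record:

* `incident_only` — earliest event on/before `patient_end`; if it precedes
  `patient_start` the patient is *rejected* as prevalent at entry;
* `incident_or_prevalent` — earliest event on/before `patient_end`, however
  early;
* `first_after_entry` — earliest event inside the observation window.

The combination logic (grammar: `expr := term (or term)*`,
`term := factor (and factor)*`, `factor := NAME | ( expr )`, case-insensitive
keywords, `and` over `or`, no NOT — negation is what exclusion entities are
for) is evaluated by a hand-written recursive-descent parser and two
evaluators:

* **loose** — an `and` contributes the later of its sides' dates; an `or`
  the earlier satisfied side. Equivalently, the index date is the earliest
  date on which the whole expression first became true; this equals the
  minimum over satisfying entity subsets of the subset's latest date, which
  the test suite checks by exhaustive enumeration.
* **strict** — within every `and` chain the written order must equal the
  temporal order (left date ≤ right date; same-day counts as in-order,
  since same-day diagnosis-plus-prescription is a real sequence). `or`
  branches are alternatives and carry no cross-branch order constraint.
  Implementation note: each node yields the *set* of achievable in-order
  completion dates over resolutions of its `or` nodes, and the earliest is
  taken. A simpler "earliest satisfied branch" recursion is wrong whenever
  the earliest branch of an `or` breaks a downstream order constraint that
  another branch would satisfy; the candidate-set recursion agrees with
  exhaustive resolution enumeration on every tested expression.

A satisfied patient becomes exposed (or a case) with the evaluated index
date. A prevalent `incident_or_prevalent` hit contributes
`max(event_date, patient_start)`: a condition already present at entry puts
the patient at risk from cohort entry, and this keeps every index date
inside the observation window. An unsatisfied patient becomes a potential
control when controls are required; in cohort/case–control designs without
controls they are rejected. In **cross-sectional designs unsatisfied
patients are retained** as unexposed population rows: a cross-sectional
dataset describes the whole eligible population on the reference date, and
discarding non-cases would leave prevalence without a denominator.

Exclusion entities then remove exposed patients (`exclude_ever` at any
time, `exclude_before_index` on or before the index day), as does the
optional pre-index outcome restriction. "Before index" is inclusive of the
index day throughout: an outcome recorded on the index date is treated as
prevalent, which is the conservative reading and complements stage 5's
strictly-after convention so that no event can be counted on both sides.

### Stage 3 — control pool

The same machinery driven by the optional control logic. Controls have no
index date yet, so only `exclude_ever` exclusions apply here; index-relative
control exclusions are matching criteria (stage 4). An absent control logic
means the unexposed group is simply "absence of the exposure" and the pool
passes through unchanged.

### Stage 4 — matching

Both the exposed list and the pool are shuffled with the seeded generator;
a single greedy pass over the shuffled exposed filters the remaining pool
through, in order: sex rule (same/any/opposite), window coverage of the
index date, age at index within ± tolerance (completed years), Townsend
equality, ethnicity equality, registration-date difference, exposure
duration (index − earliest record of the referenced entity, both arms),
baseline treatment and condition concordance (the control has a pre-index
record of each listed entity iff the exposed does), measurement proximity
(latest value within the lookback window, |difference| ≤ tolerance), and
absence of the listed outcomes/events on or before the index date. The
required number of controls is sampled uniformly without replacement,
removed from the pool, given the exposed patient's index date (the standard
guard against immortal time bias) and a shared group id.

Choices: greedy sequential matching with no global optimisation — exactly
the stated two-step randomise-then-pick procedure, and reproducible under a
seed. Registration matching uses the absolute difference of registration
dates (the alternative — registered duration at index — is a different
criterion a future version could add). Missing Townsend/ethnicity matches
only missing when that criterion is on. When the exposed patient has no
qualifying measurement in the lookback window the measurement criterion is
vacuous for that set rather than requiring controls to be missing too.
Exposed patients with zero eligible controls are kept, flagged by an empty
control list, under the default `keep_unmatched` policy (nothing in the
matching procedure says to discard them; matched-analysis users can choose
`drop_unmatched`). Unselected pool members are logged as "control not
selected" so the conservation identity covers them.

Demographic criteria are evaluated vectorized (NumPy) over the whole pool;
event-dependent criteria run per surviving candidate. A 22,000-patient
extraction with ~2,000 exposed matches in a few seconds on one core.

### Stage 5 — outcomes and exit

For each outcome entity, the first event strictly after the index date and
no later than `patient_end` is recorded. The exit date is
`min(patient_end, first of any outcome)`; per-outcome dates and
days-to-event are also emitted so analysts can apply cause-specific
censoring. Outcomes are sought strictly after index so a same-day outcome
cannot create zero-length immortal follow-up (it belongs to the pre-index
exclusion logic). Whether matched controls should additionally be censored
at their partner's exit is analysis policy, not extraction; per-patient
exits are emitted.

### Stage 6 — baselines, assembly, summaries, encryption

Baseline rules: `latest_before_index` (optionally within a lookback
window), `earliest_ever`, `first_after_index`. Valued measurement entities
yield the event value; coded entities yield presence via the event date.
The dataset has one wide row per surviving member with a deterministic
column order and sort (group id, exposed first, match order), so identical
inputs and seed give byte-identical CSV output; missing values are empty
fields, mirroring the input convention.

Summaries: person-years use 365.25 days/year. Incidence rates are reported
per 100,000 person-years with exact Poisson 95% CIs
(`χ²(α/2, 2k)/2` and `χ²(1−α/2, 2k+2)/2` scaled by person-time); zero
person-years is an error, not a zero. Prevalence on a reference date uses
everyone observed on that date as the denominator and exposed members
indexed on or before it as the numerator, with Clopper–Pearson intervals.
Stratification supports sex, 10-year age band at index, exposure group and
calendar year; yearly incidence splits each patient's person-time across
calendar years (half-open year segments, so person-time is conserved
exactly) and assigns each event to its calendar year.

Encryption: AES-256 in CTR mode with HMAC-SHA256 over header+ciphertext
(encrypt-then-MAC), keys derived from the password by PBKDF2-HMAC-SHA256
(200,000 iterations by default) over a random 16-byte salt; the container
stores a one-byte format version, the KDF iteration count, salt and nonce.
Wrong passwords and tampering raise an authentication error before any
plaintext is produced. The AES implementation is generated from the
algebraic definition of the cipher (GF(2⁸) inversion + affine map for the
S-box, T-table rounds) and is pinned to the FIPS-197 and NIST SP 800-38A
known-answer vectors in the test suite. Throughput (~0.5 MB/s) is ample for
dataset-sized payloads.

## Orchestration

The stage plan is a pure function of the design: cross-sectional designs
run stages 1, 2 and 6; cohort/case–control designs run all six, with 3–4
conditional on controls being required. After every stage the full state is
checkpointed as JSON keyed by digests of the design, the database and the
seed; `--resume` continues from the last matching checkpoint and is tested
to reproduce the uninterrupted outputs byte-for-byte from every
interruption point. Stage 4 is the only consumer of randomness and builds
its generator from the study seed at stage start, which is what makes
resumption exact. One global seed therefore controls the entire extraction.

## The synthetic generator

`SimConfig`/`generate` emulate a single-source, UK-primary-care-like
database: practices with key/collection dates, patients with a registration
lifecycle (constant-hazard deregistration at 0.02/p-y and death at
0.01/p-y, competing), uniform birth years 1930–1995, a 50/50 sex ratio,
Townsend quintiles and ethnicity with 10% missingness, and BMI/HbA1c
measurement streams at 0.25 records/p-y. The planted structure is:

* a first exposure event from a constant incidence (default 0.012/p-y,
  giving roughly one patient in ten exposed over follow-up, with an
  optional prescription event 60 days later to exercise strict sequences);
* a first outcome event from a piecewise-exponential clock — constant
  baseline hazard (default 44 per 100,000 p-y) before the exposure event
  and baseline × hazard ratio (default 3.0) after it;
* optionally, a chronic condition planted at a Bernoulli point prevalence
  (default 3.3%) with the diagnosis date drawn on or before a stated
  reference date.

Default scale is 20 practices × 1,100 patients ≈ 204,000 observed
patient-years, the scale at which the recovery checks are run: the
extracted matched-cohort unexposed rate carries an exact Poisson CI that
covers the planted 44/100,000 p-y, and the crude exposed/unexposed rate
ratio falls within Monte-Carlo error of the planted 3.0.

One recovery behaviour is worth understanding rather than "fixing":
**finite-pool depletion in without-replacement matching**. Matching
consumes controls permanently, and patients who are eligible for many
index dates — long observation windows and no outcome ever — are consumed
disproportionately early, so later exposed patients draw from a leftover
pool enriched in patients whose outcome lies ahead of them. At the default
study conditions roughly 45% of the potential-control pool ends up
consumed (≈2,000 exposed × 4 controls from a pool of ≈18,000), and the
matched-control rate runs ≈20% above the planted hazard (the recovered
rate ratio correspondingly trends below the planted 3.0, while the exposed
rate is recovered without bias). Dropping the sampling fraction to ≈10%
(one control per exposed, or a larger pool) removes the effect entirely —
pooled over seeds the control rate is then within 0.1 SE of the planted
44/100,000 p-y. This is a property of the selection procedure itself,
invisible at the multi-million-patient scale of licensed databases
where the pool dwarfs the exposed group, and it is why the recovery
criteria are stated as confidence-interval coverage and Monte-Carlo error
bands rather than point equality.

Constant hazards were chosen deliberately: the pipeline's correctness
claims concern extraction, not survival-model realism, and closed-form
expected rates make every tolerance computable. What the generator does
**not** emulate — and what passing recovery tests therefore do not
demonstrate — includes age- and deprivation-dependent hazards, informative
censoring, miscoding and code-hierarchy noise, duplicate/conflicting
records, practice-level clustering of data quality, and time-varying
exposure status. Real-database behaviour additionally depends on code-list
(phenotype) quality, which is entirely outside the tool.

`worked_toy()` is a fixed, hand-constructed 40-patient database containing
every edge case (prevalent exposure at entry, out-of-order strict
sequences, a pre-index outcome one day before index, an exclusion event
after follow-up ends, a year-precision birth date, a Feb-29 birthday,
deaths, deregistrations, a practice entirely outside the study period).
Its extraction output under the documented design is frozen as golden
files; every matched pair in it is re-verified by an independent
criterion-by-criterion checker.

## Numerical and degenerate-input choices

* Date ties everywhere break deterministically by (date, code, source
  table).
* An empty database extracts to an empty dataset with an all-zero attrition
  table that still passes the conservation check.
* `registration_tolerance_days`, lookbacks and tolerances are closed
  bounds (≤).
* Event values are floats; measurement matching uses absolute differences.
* Group ids are consecutive integers in shuffled processing order; the
  order is reconstructable from the seed recorded in the extraction log.

## Known limitations

Single-source databases only (no multi-source merging or common-data-model
mapping); no NOT operator or inter-entity gap constraints ("A then B within
90 days") in the combination grammar; no new-user/prevalent-new-user
pharmaco-epidemiological designs; no propensity or nearest-neighbour
matching; first occurrences only for outcomes (no recurrent events or
competing-risk machinery). These are extraction-scope boundaries, not
statistical-analysis features the tool half-implements: the output is an
analysable dataset, and modelling belongs downstream.
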