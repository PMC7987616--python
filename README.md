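# ehrcohort

Automated, auditable extraction of analysable study datasets — cohort,
case–control and cross-sectional — from longitudinal primary-care-style
electronic health records.

Assembling a study dataset from a primary-care database (THIN/CPRD-like
structure: practices, registered patients, coded diagnoses, prescriptions
and measurements) is traditionally a bespoke, manual process: eligibility
windows, exposure definitions, control selection, matching and baseline
extraction are re-implemented per study, with no systematic account of why
each excluded patient was dropped. `ehrcohort` implements that process as a
declarative, six-stage ETL pipeline:

1. **Eligible period** — per-practice intervals from data-quality key
   dates; per-patient observation windows
   `[max(registration+lead-in, practice start, min-age date),
   min(practice end, deregistration, death, max-age date)]`.
2. **Exposure / case definition** — named *code entities* (bundles of
   clinical codes with incident/prevalent semantics) combined by a boolean
   grammar (`and`/`or`, parentheses, `and` binds tighter), evaluated by a
   recursive-descent parser in *loose* mode (index date = latest event
   among the entities needed, i.e. the earliest date the criterion became
   true) or *strict* mode (the entities must occur in the written order, or
   the patient is rejected).
3. **Control pool** — patients failing the exposure logic, optionally
   refined by their own logic.
4. **Matching** — seeded, randomized, without-replacement selection of
   controls per exposed on sex, age (±years at index), Townsend,
   ethnicity, registration date, exposure duration, baseline
   conditions/treatments, measurement values (± tolerance within a
   lookback) and pre-index exclusions. Matched controls inherit the
   exposed patient's index date, the standard guard against immortal time
   bias.
5. **Outcomes & exit** — first event of each outcome strictly after index;
   exit = `min(patient end, first outcome)`.
6. **Assembly** — baseline variables, one wide row per patient,
   deterministic bytes for a fixed seed, optional AES-256 (CTR +
   HMAC-SHA256, password-derived keys) encryption.

Every rejected patient is counted under a documented reason per stage, and
the pipeline enforces conservation — `dataset rows + Σ rejections =
input population` — as a hard error, so the resulting attrition table is a
verifiable audit of the extraction. Summary epidemiology (incidence per
100,000 person-years with exact Poisson CIs, point prevalence with exact
binomial CIs, stratified by sex/age band/exposure/calendar year) is built
in, as is a seeded synthetic-EHR generator with planted exposure
incidence, outcome hazards (piecewise-exponential, hazard ratio applied
after the first exposure event) and point prevalence, so the whole chain
is testable without licensed data.

It is intended for epidemiologists and health-data scientists who want
reproducible, declarative extractions, and for methodologists who need a
transparent reference implementation of matched-cohort extraction
mechanics.

## A worked example

The package ships a fixed 40-patient toy database covering the awkward
cases (prevalent exposure, out-of-order sequences, pre-index outcomes,
year-precision birth dates). `python examples/run_worked_example.py`
extracts an incident type-2-diabetes-then-metformin cohort (strict order)
with two age/sex-matched controls per exposed patient:

```
patients in database: 40
rows in analysable dataset: 15
attrition verdict (rows + rejections == input): True

Attrition table — every removed patient, by stage and reason:
 stage                               reason  count
stage1           age at entry above maximum      1
stage1      no overlap with practice window      2
stage1                practice window empty      2
stage2 exclusion (Amputation) ever recorded      1
stage2              exposure order violated      1
stage2        outcome (Stroke) before index      1
stage2    prevalent at entry: Type2Diabetes      2
stage4                 control not selected     15
```

Reading it: 40 patients entered; 5 fell at stage 1 (two in a practice whose
collection window misses the study period, one too old at entry, two never
observed inside their practice's window); 5 fell at stage 2 (two with
diabetes already present at cohort entry under an incident-only
definition, one prescribed metformin *before* the diabetes diagnosis under
strict ordering, one with an amputation ever recorded, one with a stroke
the day before the index date); 15 unexposed patients were never selected
as controls. The remaining 15 rows are 5 exposed patients and their 10
matched controls, each control carrying its exposed partner's index date:

```
patient_id  group_id  exposed_flag index_date  exit_date  follow_up_days  BMI_value
     pt002         1             1 2006-09-10 2018-05-01            4251        NaN
     pt008         1             0 2006-09-10 2014-09-01            2913        NaN
     ...
     pt001         4             1 2007-06-15 2010-02-10             971       30.2
```

`pt001` exits at the first ischemic-heart-disease event 971 days after
index; the BMI column holds the latest value within the 735-day baseline
lookback (missing where no such measurement exists).

Other entry points: `examples/simulate_and_recover.py` (planted-rate
recovery at ~200,000 patient-years), `examples/prevalence_survey.py`
(cross-sectional mode), `examples/encrypt_dataset.py`, and a CLI —

```bash
ehrcohort simulate --toy --out db/
ehrcohort extract --database db/ --design examples/designs/matched_cohort.yaml --out out/
ehrcohort summarise --dataset out/dataset.csv --mode incidence --by exposed
```

The design-file schema is documented by the annotated example in
`examples/designs/matched_cohort.yaml`.

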