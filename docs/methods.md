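# Methods

`diabeqc` implements a three-stage evaluation of quality of care (QC) for
type 2 diabetes mellitus (T2DM) in multi-clinic primary care, driven by a
flat-file EHR extract: (1) expert-panel selection of indicators, (2) cohort
construction with data-quality screening, (3) computation of process and
outcome indicators per clinic and pooled. Because no patient-level extract
can be distributed, the package includes a synthetic EHR generator that
reproduces the statistical structure the pipeline assumes, so every stage is
exercised and validated end to end.

## Stage 1 — panel rating aggregation

Candidate indicators are scored by a panel (eight experts in the motivating
setting) on two domains, validity and feasibility, each on a 1–9 scale. A
candidate is **accepted** when its mean score is ≥ 7 on *both* domains. Two
conventions matter for reproducibility and are fixed here:

* the threshold is inclusive — candidates whose feasibility mean is exactly
  7.0 are accepted (the published decisions force this reading);
* classification operates on means rounded half-up to one decimal, the
  precision at which panel results are reported. Python's banker's rounding
  is deliberately not used anywhere a table cell is produced.

Multi-round workflows are represented as repeated rating sheets with round
labels; the decision uses the final round. No disagreement index from the
full RAND/UCLA manual is computed, because the acceptance rule in this design
is the two-domain mean threshold only.

The packaged catalog (`data/indicator_catalog.yaml`) carries all 23
candidates with their published domain means, accept/discard status and a
`programmable` flag. 18 candidates are accepted; 14 of those are computable
from structured EHR fields and form the active catalog. The four free-text
indicators (smoking counseling, exercise advice, two adherence
registrations) and the five discarded candidates remain as inactive entries;
evaluating an inactive entry raises an error rather than silently returning
a rate.

## Stage 2 — cohort and data cleaning

**Eligibility.** A patient enters the cohort iff (a) a T2DM code — E111–E119,
E140–E149 or E14X — appears in any of the three EHR diagnosis slots at any
date up to the window end, (b) age at the window start is ≥ 20 completed
years ("older than 19"), and (c) at least one family-doctor visit falls in
the observation window (calendar 2009 by default). Age is computed at the
window start; the alternative anchors (at visit, at year end) are defensible,
and the choice is configurable through the criteria object. ICD-10 matching
is exact against the enumerated set after uppercasing and dot removal
(`E11.2 ≡ E112`); `E14X` also matches the bare stem `E14`, since coding
dialects differ on unspecified fourth characters. Excluded T2DM-coded
patients are logged with a single reason (age is checked before visits).

**Plausibility screening.** Measurements outside predefined biological
bounds are treated as data errors and excluded everywhere: systolic
50–250 mmHg, diastolic 40–200 mmHg, height 130–250 cm, weight 30–200 kg
retained; HbA1c < 3.0 %, fasting glucose < 37 mg/dl and total cholesterol
< 100 mg/dl excluded (no upper bounds for the analytes by default, since the
screening rules specify only lower limits there; upper bounds are
configurable). The bounds themselves are retained — exclusion is strictly
outside. A blood-pressure *pair* is dropped when either component is missing
or implausible. Every removal is logged.

**Other conventions.** Comorbidities (hypertension I10–I15, dyslipidemia
E78, other cardiovascular disease I20–I25/I50, smoking F17/Z72.0) are
medical history with unlimited lookback; the dyslipidemia-screening
indicator additionally distinguishes diagnoses dated strictly before the
window start. Chronic complications are read from the fourth character of
the diabetes codes (E11.2 nephropathy, E11.3 retinopathy, E11.4 neuropathy,
E11.5 peripheral vascular) and from the dedicated codes N08.3, H36.0, G63.2
and I73. Same-day duplicate measurements keep the last-loaded record and log
the drop. BMI = weight/height² (kg/m²), reported to two decimals, computed
at the earliest and latest in-window date with both components plausible;
categories are the standard half-open bins (< 18.5, 18.5–24.9, 25.0–29.9,
≥ 30). Diabetes duration is window-start year minus onset year when onset is
recorded, otherwise missing — missing data are excluded from the relevant
denominators, never imputed.

## Stage 3 — indicator evaluation

Each active indicator is a denominator predicate and a numerator predicate
over the cleaned timeline, evaluated to a tri-state per patient (not in
denominator / denominator only / numerator). Conventions:

* **"Last three visits"** (pharmacological indicators): the drug counts if
  prescribed on at least one of the patient's last three distinct
  family-doctor visit dates in the window. The acetylsalicylic-acid
  indicator additionally requires a daily dose in [75, 150] mg.
* **"Last 3 measurements"** (outcome indicators): evaluated over the last
  `min(3, n)` cleaned values; eligibility requires at least one. Requiring a
  full three would shrink the outcome denominators far below what annual
  laboratory coverage (~60 % of patients with any result) can support, so
  ≥ 1 is the weakest consistent reading; the helper is explicit (`last_k`)
  and the requirement could be tightened by changing the denominator rule.
* **Contraindications** ("unless contraindicated") remove the patient from
  the denominator, the standard quality-measure convention, rather than
  counting as failures.
* **Undetermined** measurement states (no relevant measurement at all) map
  to "not in denominator".
* The **composite outcome** denominator is the intersection of the glycemic,
  cholesterol and blood-pressure denominators; its numerator requires all
  three targets simultaneously.
* The **weight-loss** indicator uses the first and last in-window weights
  (≥ 2 dated weights required) and credits a relative change ≤ −5 %;
  baseline overweight/obesity is judged at the first in-window BMI.
* A clinic with **no laboratory capacity** for an analyte (no resulted HbA1c
  anywhere in its cohort) is rendered "Not available" at the clinic level
  but still contributes its full denominator — with a zero numerator — to
  the pooled rate. This is the only reading under which a pooled
  measurement rate over all clinics is meaningful when capacity differs.

Pooled rates are 100 × Σ numerators / Σ denominators (not the unweighted
mean of clinic rates). All percentages stay unrounded internally and are
rounded half-up to one decimal at render time only.

`report.pooled_from_rates` recovers a pooled percentage from printed
per-clinic (rate, denominator) pairs; it equals the engine's pooled rate
whenever clinic rates are computed unrounded from the same counts, and is
used to reproduce published pooled totals from published clinic values. One
published row (ACEi/ARB in hypertension) has a pooled total that is not
consistent with its own printed clinic values (weighted pooling gives 55.3 %
against a printed 57.4 %, and the printed pooled denominator differs from
the sum of the clinic denominators); the packaged data flags that row rather
than forcing it.

## Synthetic EHR generator

The generator emulates the study-like population: per clinic, a member roll,
Bernoulli attendance, and among adult attendees a configurable T2DM
prevalence (default 0.144). T2DM patients draw age from N(62.3, 12.9)
truncated to [21, 99], 58.5 % female, comorbidity prevalences
{hypertension 0.604, dyslipidemia 0.416, other CVD 0.092, any chronic
complication 0.317}, and a family-doctor visit count from a negative
binomial matched to mean 8.8 and sd 4.6, truncated to ≥ 1 (the attendee
definition) and capped at 60. BMI categories default to
{under 0.004, normal 0.183, overweight 0.419, obese 0.394} — the observed
distribution renormalised over non-missing — and weights/heights are drawn
inside each category with a margin so that storage rounding cannot flip the
recomputed category at a band edge. Two of four clinics lack HbA1c capacity
by default.

Values the source tables do not pin down were chosen once as field-plausible
and are stated here: smoking prevalence 0.10; probability of a fasting
glucose result 0.55 (so that roughly 60 % of patients have any glycemic
result, matching the reported laboratory coverage); contraindication
prevalence 0 by default (the published metformin denominator is
indistinguishable from the overweight/obese count, implying negligible
contraindication coding); drug-product synonyms and background prescriptions
(glibenclamide, insulin) are decorative realism that no indicator tests.

**Eligibility-then-adherence.** Eligibility attributes are drawn first; each
indicator's numerator event is then emitted with its configured adherence
probability conditional on eligibility (default adherence values follow the
published pooled rates). Controlled/uncontrolled outcome values are generated
so the engine's reading is unambiguous: a controlled patient's values all sit
inside the target, an uncontrolled patient's *last* value sits outside it.
The generator records per-patient ground truth (eligible and numerator flags
for all 14 indicators) in a sidecar; the pipeline's counts must — and in the
tests do — match the sidecar exactly, before any rounding.

**Defect injection** is a separate, explicit step so the clean bundle and
its ground truth stay exact. Field-level missingness defaults follow the
observed rates (schooling 0.287, marital status 0.310, employment 0.426,
diabetes duration 0.645, BMI components 0.143); implausible-value rates for
vitals default to values spanning the reported 5–24 % contamination range.
Injected values fall strictly outside the plausibility bounds (with a margin
against storage rounding), so the cleaning stage removes exactly the
injected set — the tests assert set equality against the defect log. Record
counts are never altered, and a vitals record always retains at least one
measurement. All generation is driven by a single seed; identical seeds give
byte-identical written extracts.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: joint distributions among comorbidities
(independence is assumed; simulated joint prevalences are not those of the
study), disease progression or multi-year trajectories, correlation between
visit frequency and severity, informative missingness (defects are injected
independently at random, whereas real missingness is structured), free-text
fields, and patients appearing at two clinics. Parameter-recovery results on
synthetic data validate the *engine logic*, not the published patient-level
cell values, which cannot be recomputed without the source records.

## Problem sizes and numerical choices

The default analysis configuration is 4 clinics × 3,000 members at 30 %
attendance (≈ 3,600 attendees, ≈ 500 cohort patients), which keeps the
scripted run near-instant while leaving every denominator populated. The
parameter-recovery check uses 4 × 14,000 members at 90 % attendance
(≈ 50,000 attendees, ≈ 7,400 cohort patients) so that every configured
indicator, including the smallest-denominator one (statins in
hypercholesterolemia, ≈ 28 % of the cohort), has ≥ 2,000 eligible patients;
recovery is asserted within 3 binomial standard errors of the configured
rate. Oracle-equivalence checks run 100 seeded bundles of ≤ 50 patients with
randomised adherence, 25 % contraindication prevalence and (on alternate
seeds) injected defects, against brute-force re-implementations of cohort
selection and all 14 indicators written as independent naive scans.

Ties and degenerate inputs: same-day duplicates keep the last-loaded record;
an empty cohort yields 0/0 counts rendered as missing; an empty measurement
series is "undetermined"; unknown drugs normalise to `other`; unknown
measures raise a configuration error rather than passing silently.

## Known limitations

* The engine evaluates one observation year; multi-year trend analysis is
  out of scope.
* No statistical inference across clinics (the design is descriptive).
* No record linkage or deduplication across clinics.
* The "last 3 measurements" ≥ 1 convention and the age anchor at window
  start are documented choices; alternative readings change outcome
  denominators and would need to be set explicitly in the criteria/rules.
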