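# diabeqc

Quality-of-care (QC) indicators for type 2 diabetes mellitus (T2DM) computed
from routine primary-care EHR extracts, for health-services researchers and
quality teams working with multi-clinic systems where laboratory capacity
and data completeness vary by site.

The package implements a three-stage pipeline:

1. **Panel rating aggregation** (`diabeqc.panel`) — candidate indicators are
   scored 1–9 by an expert panel on validity and feasibility; a candidate is
   accepted iff both domain means are ≥ 7 (inclusive, at one-decimal
   precision). Of the 23 packaged candidates, 18 are accepted and 14 are
   programmable from structured EHR fields.
2. **Cohort construction** (`diabeqc.cohort`) — patients with a T2DM ICD-10
   code (E11.1–E11.9, E14.0–E14.9, E14.X) in any of three diagnosis slots,
   aged ≥ 20 at the window start, with ≥ 1 family-doctor visit in the
   observation year. Measurements outside biological plausibility bounds
   (e.g. systolic < 50 or > 250 mmHg, weight < 30 or > 200 kg, HbA1c < 3 %)
   are excluded and logged.
3. **Indicator evaluation** (`diabeqc.indicators`, `diabeqc.report`) — each
   indicator is a denominator/numerator predicate pair over a cleaned
   patient timeline. For indicator *j* with per-clinic counts
   (nᵢⱼ, dᵢⱼ), the clinic rate is 100·nᵢⱼ/dᵢⱼ and the pooled rate is
   100·Σᵢnᵢⱼ / Σᵢdᵢⱼ (denominator-weighted, not the mean of clinic rates).
   Contraindications remove patients from denominators; "last three visits"
   and "last 3 measurements" windows follow the catalog conventions
   documented in `docs/methods.md`.

Because patient-level source data cannot be distributed, `diabeqc.simulate`
generates synthetic multi-clinic bundles with the structure the analysis
assumes (configurable T2DM prevalence, comorbidity rates, visit counts,
per-indicator adherence, per-clinic HbA1c capacity, field missingness and
5–24 % implausible-vitals contamination), together with a ground-truth
sidecar that the pipeline must match exactly.

## Worked example

Generate a four-clinic synthetic extract, build the cohort and evaluate the
catalog:

```python
from diabeqc import SimulationConfig, simulate_with_truth, select_cohort, evaluate_all

cfg = SimulationConfig(n_clinics=4, members_per_clinic=3000,
                       attendance_probability=0.30, seed=11)
bundle = simulate_with_truth(cfg).bundle
cohort = select_cohort(bundle)
for r in evaluate_all(cohort):
    p = r.pooled()
    print(f"{r.indicator_id:3} {p.numerator:4}/{p.denominator:<4} "
          f"{'' if p.percentage() is None else round(p.percentage(), 1)}")
```

Output:

```
p1    35/479  7.3
p2   136/479  28.4
p3    62/479  12.9
p4   155/271  57.2
p5    17/479  3.5
p6   250/388  64.4
p7   166/293  56.7
p8   162/369  43.9
p9    61/122  50.0
o1    68/272  25.0
o2   153/275  55.6
o3    55/479  11.5
o4    48/380  12.6
o5     2/160  1.2
```

Reading: of the 479 cohort patients, 35 (7.3 %) had an HbA1c result (`p1`;
two of the four clinics lack the assay and count toward the denominator with
zero numerators), 64.4 % of eligible overweight/obese patients received
metformin at one of their last three visits (`p6`), 11.5 % met the
< 130/80 mmHg blood-pressure target in their last three measurements (`o3`),
and only 1.2 % met the composite glycemia + cholesterol + blood-pressure
target (`o5`). Denominators differ per indicator because eligibility,
measurement availability and contraindications differ.
`analysis/04_evaluate_indicators.py` runs the same evaluation after
injecting the data-quality defects, so its rates differ slightly.

The numbered scripts under `analysis/` run the full narrative —
`01_panel_review.py` (panel decisions), `02_simulate_ehr.py` (extract +
defects, written under `scratch/`), `03_build_cohort.py`,
`04_evaluate_indicators.py`, `05_describe_cohort.py` (descriptive tables)
and `06_reproduce_published_pooling.py` (pooled totals recomputed from
published per-clinic rates) — and write their tables under `results/`.

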