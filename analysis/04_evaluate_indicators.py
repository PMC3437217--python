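#!/usr/bin/env python
"""Stage 3a: evaluate the 14 active quality indicators over the cohort.

Reads the defected synthetic extract, evaluates every active indicator per
clinic and pooled, and writes results/indicator_results.{csv,json}. Clinics
with no HbA1c capacity render as "Not available" for the HbA1c-measured
indicator while still contributing their denominators to the pooled total.
Run 02 first.
"""

from pathlib import Path

from diabeqc.cohort import select_cohort
from diabeqc.indicators import evaluate_all
from diabeqc.io import TABLE_FILENAMES, read_ehr_bundle
from diabeqc.report import render_report, results_to_records

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    src = ROOT / "scratch" / "synthetic_ehr_defected"
    paths = {t: src / f for t, f in TABLE_FILENAMES.items() if (src / f).exists()}
    cohort = select_cohort(read_ehr_bundle(paths))
    results = evaluate_all(cohort)

    out_csv = render_report(results, "csv", ROOT / "results" / "indicator_results.csv")
    render_report(results, "json", ROOT / "results" / "indicator_results.json")

    print(f"cohort: {cohort.size()} patients in {len(cohort.clinic_counts())} clinics\n")
    print(f"{'indicator':<10} {'pooled n/d':>13} {'rate %':>8}")
    for rec in results_to_records(results):
        pooled = f"{rec['total_percentage']}"
        num_den = next(
            (
                f"{r.pooled().numerator}/{r.pooled().denominator}"
                for r in results
                if r.indicator_id == rec["indicator_id"]
            )
        )
        print(f"{rec['indicator_id']:<10} {num_den:>13} {pooled:>8}")
    print(f"\nwrote {out_csv.relative_to(ROOT)} and the JSON rendering")


if __name__ == "__main__":
    main()
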