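#!/usr/bin/env python
"""Stage 3b: descriptive tables for the synthetic cohort.

Writes per-clinic and total distributions of demographics, clinical
conditions (comorbidity, complications, nutritional status with explicit
missing-data rows) and care characteristics to results/cohort_description_*.
Run 02 first.
"""

from pathlib import Path

from diabeqc.cohort import select_cohort
from diabeqc.io import TABLE_FILENAMES, read_ehr_bundle
from diabeqc.report import describe_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    src = ROOT / "scratch" / "synthetic_ehr_defected"
    paths = {t: src / f for t, f in TABLE_FILENAMES.items() if (src / f).exists()}
    cohort = select_cohort(read_ehr_bundle(paths))
    tables = describe_cohort(cohort)
    for name, table in tables.items():
        out = ROOT / "results" / f"cohort_description_{name}.csv"
        table.to_csv(out)
        print(f"wrote {out.relative_to(ROOT)}  ({table.title})")
    general = tables["general"].data
    print(f"\ncohort: {int(general.loc['Patients (n)', 'Total'])} patients")
    print(f"female: {general.loc['Female sex: female', 'Total']}%")
    print(f"age:    {general.loc['Age, mean (sd)', 'Total']}")


if __name__ == "__main__":
    main()
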