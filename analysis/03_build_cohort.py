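#!/usr/bin/env python
"""Stage 2b: select the T2DM cohort from the defected synthetic extract.

Reads the flat-file tables written by 02_simulate_ehr.py, applies the
eligibility criteria (T2DM code in any diagnosis slot, age >= 20 at the
window start, >= 1 family-doctor visit in 2009) and the plausibility filters,
and writes the exclusion log. Run 02 first.
"""

from pathlib import Path

from diabeqc.cohort import select_cohort
from diabeqc.io import TABLE_FILENAMES, read_ehr_bundle, write_load_log

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    src = ROOT / "scratch" / "synthetic_ehr_defected"
    paths = {t: src / f for t, f in TABLE_FILENAMES.items() if (src / f).exists()}
    bundle = read_ehr_bundle(paths)
    cohort = select_cohort(bundle)

    counts = cohort.clinic_counts()
    removed = sum(
        1 for t in cohort.timelines for e in t.cleaning_log if e["issue"] == "implausible"
    )
    write_load_log(
        [{"patient_id": pid, "reason": r} for pid, r in sorted(cohort.exclusion_log.items())],
        src / "exclusion_log.jsonl",
    )

    print(f"attendees loaded      : {len(bundle.patients)}")
    print(f"cohort size           : {cohort.size()} "
          f"({100 * cohort.size() / len(bundle.patients):.1f}% of attendees)")
    for cid in sorted(counts):
        print(f"  {cid}: {counts[cid]}")
    print(f"excluded T2DM-coded   : {len(cohort.exclusion_log)}")
    print(f"implausible values dropped by cleaning: {removed}")
    print(f"wrote {src.relative_to(ROOT)}/exclusion_log.jsonl")


if __name__ == "__main__":
    main()
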