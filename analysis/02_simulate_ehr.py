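#!/usr/bin/env python
"""Stage 2a: generate the synthetic multi-clinic EHR extract.

Simulates four family-medicine clinics with the default study-like structure
(~14.4% T2DM prevalence among adult attendees, HbA1c capacity in two of four
clinics), writes the clean extract, a defected copy with realistic
missingness and implausible vitals, the ground-truth sidecar and the defect
log under scratch/synthetic_ehr*/ (bulky, regenerable).
"""

import json
from pathlib import Path

from diabeqc.io import write_analytic_dataset
from diabeqc.simulate import (
    SimulationConfig,
    inject_data_defects,
    simulate_with_truth,
    write_truth_sidecar,
)

ROOT = Path(__file__).resolve().parents[1]
SEED = 11


def main() -> None:
    cfg = SimulationConfig(n_clinics=4, members_per_clinic=3000, attendance_probability=0.30, seed=SEED)
    res = simulate_with_truth(cfg)
    bundle = res.bundle

    clean_dir = ROOT / "scratch" / "synthetic_ehr"
    write_analytic_dataset(bundle, clean_dir)
    write_truth_sidecar(res.truth, clean_dir / "ground_truth.json")

    defected, log = inject_data_defects(bundle, cfg)
    defect_dir = ROOT / "scratch" / "synthetic_ehr_defected"
    write_analytic_dataset(defected, defect_dir)
    (defect_dir / "defect_log.json").write_text(
        json.dumps({"missing": log.missing, "implausible": log.implausible}, indent=1) + "\n"
    )

    print(f"seed                 : {SEED}")
    print(f"attendees            : {len(bundle.patients)}")
    print(f"T2DM patients        : {len(res.truth)}")
    print(f"visits / vitals / labs: {len(bundle.visits)} / {len(bundle.vitals)} / {len(bundle.labs)}")
    print(f"injected missing fields      : {len(log.missing)}")
    print(f"injected implausible values  : {len(log.implausible)}")
    print(f"wrote {clean_dir.relative_to(ROOT)}/ and {defect_dir.relative_to(ROOT)}/")


if __name__ == "__main__":
    main()
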