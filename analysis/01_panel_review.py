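#!/usr/bin/env python
"""Stage 1: aggregate the expert-panel ratings of candidate indicators.

Applies the acceptance rule (mean validity and mean feasibility both >= 7 on
the 1-9 scale) to the packaged catalog of 23 candidates and writes the
decisions to results/panel_decisions.csv.
"""

import csv
from pathlib import Path

from diabeqc.indicators import load_catalog_metadata
from diabeqc.panel import classify_candidate

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    entries = load_catalog_metadata()
    out = ROOT / "results" / "panel_decisions.csv"
    out.parent.mkdir(exist_ok=True)
    rows = []
    for e in entries:
        status = classify_candidate(e["validity_mean"], e["feasibility_mean"]).value
        rows.append(
            {
                "candidate_id": e["id"],
                "family": e["family"],
                "mean_validity": e["validity_mean"],
                "mean_feasibility": e["feasibility_mean"],
                "decision": status,
                "programmable": e["programmable"],
                "title": e["title"],
            }
        )
    with open(out, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)

    accepted = [r for r in rows if r["decision"] == "accepted"]
    active = [r for r in accepted if r["programmable"]]
    print(f"candidates reviewed : {len(rows)}")
    print(f"accepted            : {len(accepted)}")
    print(f"discarded           : {len(rows) - len(accepted)}")
    print(f"programmable (active): {len(active)}")
    print(f"wrote {out.relative_to(ROOT)}")


if __name__ == "__main__":
    main()
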