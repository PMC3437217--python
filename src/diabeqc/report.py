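"""Report tables: cohort description, indicator results, pooled-rate utilities.

Percentages are kept unrounded internally and rounded half-up to one decimal
only at render time. A clinic that cannot measure an indicator (no laboratory
capacity for the analyte) renders as "Not available" at the clinic level while
still contributing its full denominator to the pooled total.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .cohort import BMI_CATEGORIES, COMPLICATION_TYPES, Cohort, PatientTimeline
from .indicators import IndicatorResult
from .model import HYPOGLYCEMIC_DRUGS, Employment, InsuranceRole, MaritalStatus, Schooling, Sex
from .util import round_half_up

NOT_AVAILABLE = "Not available"

AGE_GROUPS = ("<30", "30-39", "40-49", "50-59", "60-69", ">=70")


def pooled_from_rates(clinic_rates: list[float], clinic_denominators: list[int]) -> float:
    """Denominator-weighted pooling of per-clinic percentages, half-up to 1 dp.

    This is the pooled rate 100 * sum(n_i) / sum(d_i) recovered from printed
    clinic-level (rate, denominator) pairs: each clinic's numerator is
    rate/100 * denominator. Used to reproduce published pooled totals from
    published per-clinic values.
    """
    if len(clinic_rates) != len(clinic_denominators):
        raise ValueError("rates and denominators must have equal length")
    if not clinic_rates:
        raise ValueError("at least one clinic required")
    if any(d <= 0 for d in clinic_denominators):
        raise ValueError("denominators must be positive")
    total = sum(r / 100.0 * d for r, d in zip(clinic_rates, clinic_denominators))
    return round_half_up(100.0 * total / sum(clinic_denominators), 1)


def load_published_results() -> dict:
    """The packaged per-clinic published results (rates and denominators)."""
    text = resources.files("diabeqc.data").joinpath("published_results.yaml").read_text("utf-8")
    return yaml.safe_load(text)


@dataclass
class ReportTable:
    title: str
    data: pd.DataFrame  # rows = labels, columns = clinics + "Total"

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="row")


def _age_group(age: int) -> str:
    if age < 30:
        return "<30"
    if age >= 70:
        return ">=70"
    lo = (age // 10) * 10
    return f"{lo}-{lo + 9}"


def _pct_rows(
    groups: dict[str, list[PatientTimeline]],
    labels: list[str],
    key,
    prefix: str = "",
) -> dict[str, dict[str, float]]:
    """Percentage distribution of ``key(t)`` (a label or list of labels) per column."""
    rows: dict[str, dict[str, float]] = {f"{prefix}{lab}": {} for lab in labels}
    for col, ts in groups.items():
        n = len(ts)
        counts = {lab: 0 for lab in labels}
        for t in ts:
            got = key(t)
            for lab in got if isinstance(got, (list, set, frozenset, tuple)) else [got]:
                if lab in counts:
                    counts[lab] += 1
        for lab in labels:
            rows[f"{prefix}{lab}"][col] = round_half_up(100.0 * counts[lab] / n, 1) if n else None
    return rows


def _mean_sd(values: list[float]) -> str:
    if not values:
        return NOT_AVAILABLE
    s = pd.Series(values, dtype=float)
    return f"{round_half_up(float(s.mean()), 1)} ({round_half_up(float(s.std(ddof=1)), 1) if len(s) > 1 else 0.0})"


def describe_cohort(cohort: Cohort) -> dict[str, ReportTable]:
    """Descriptive tables per clinic and total: demographics, clinical
    conditions, and care characteristics, with explicit missing-data rows."""
    groups: dict[str, list[PatientTimeline]] = dict(sorted(cohort.by_clinic().items()))
    groups["Total"] = cohort.timelines
    cols = list(groups)

    def assemble(rows: dict[str, dict]) -> pd.DataFrame:
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)

    # --- general characteristics ---------------------------------------
    general: dict[str, dict] = {}
    general["Patients (n)"] = {c: len(ts) for c, ts in groups.items()}
    general.update(
        _pct_rows(groups, ["female"], lambda t: "female" if t.sex is Sex.FEMALE else "other", "Female sex: ")
    )
    general["Age, mean (sd)"] = {c: _mean_sd([t.age_years for t in ts]) for c, ts in groups.items()}
    general.update(_pct_rows(groups, list(AGE_GROUPS), lambda t: _age_group(t.age_years), "Age "))
    general.update(
        _pct_rows(
            groups,
            [s.value for s in Schooling],
            lambda t: t.schooling.value,
            "Schooling: ",
        )
    )
    general.update(
        _pct_rows(
            groups,
            [s.value for s in MaritalStatus],
            lambda t: t.marital_status.value,
            "Marital status: ",
        )
    )
    general.update(
        _pct_rows(
            groups,
            [s.value for s in Employment],
            lambda t: t.employment.value,
            "Employment: ",
        )
    )
    general.update(
        _pct_rows(
            groups,
            [s.value for s in InsuranceRole],
            lambda t: t.insurance_role.value,
            "Insurance: ",
        )
    )

    # --- clinical conditions -------------------------------------------
    def duration_band(t: PatientTimeline) -> str:
        d = t.diabetes_duration_years
        if d is None:
            return "missing"
        if d < 5:
            return "<5"
        if d <= 10:
            return "5-10"
        if d <= 15:
            return "11-15"
        return ">15"

    clinical: dict[str, dict] = {}
    clinical.update(
        _pct_rows(groups, ["<5", "5-10", "11-15", ">15", "missing"], duration_band, "Diabetes duration (y): ")
    )
    clinical.update(
        _pct_rows(
            groups,
            ["hypertension", "other_cvd", "dyslipidemia"],
            lambda t: list(t.comorbidities),
            "Comorbidity: ",
        )
    )
    clinical.update(
        _pct_rows(
            groups,
            ["any"],
            lambda t: "any" if t.complications else "none",
            "Chronic complication: ",
        )
    )
    clinical.update(
        _pct_rows(groups, list(COMPLICATION_TYPES), lambda t: list(t.complications), "Complication: ")
    )
    clinical.update(
        _pct_rows(
            groups,
            list(BMI_CATEGORIES) + ["missing"],
            lambda t: t.bmi_last[1] if t.bmi_last else "missing",
            "Nutritional status (end of year): ",
        )
    )

    # --- care characteristics ------------------------------------------
    care: dict[str, dict] = {}
    care["Family-doctor visits, mean (sd)"] = {
        c: _mean_sd([t.visit_count() for t in ts]) for c, ts in groups.items()
    }

    def hypoglycemic_count(t: PatientTimeline) -> str:
        drugs = {
            drug
            for rx_list in t.prescriptions_by_date.values()
            for drug, _ in rx_list
            if drug in HYPOGLYCEMIC_DRUGS
        }
        n = len(drugs)
        return str(n) if n < 3 else ">=3"

    care.update(
        _pct_rows(groups, ["0", "1", "2", ">=3"], hypoglycemic_count, "Hypoglycemic drugs: ")
    )

    def drug_types(t: PatientTimeline) -> list[str]:
        return [
            drug.value
            for rx_list in t.prescriptions_by_date.values()
            for drug, _ in rx_list
            if drug in HYPOGLYCEMIC_DRUGS
        ]

    def distinct_drug_types(t: PatientTimeline) -> set[str]:
        return set(drug_types(t))

    care.update(
        _pct_rows(
            groups,
            [d.value for d in sorted(HYPOGLYCEMIC_DRUGS, key=lambda d: d.value)],
            distinct_drug_types,
            "Drug: ",
        )
    )

    return {
        "general": ReportTable("Patients' general characteristics", assemble(general)),
        "clinical": ReportTable("Clinical conditions", assemble(clinical)),
        "care": ReportTable("Health care characteristics", assemble(care)),
    }


# ---------------------------------------------------------------------------
# indicator result rendering


def results_to_records(results: list[IndicatorResult]) -> list[dict]:
    """Flatten indicator results into render-ready records (deterministic)."""
    records = []
    for res in results:
        rec: dict = {"indicator_id": res.indicator_id, "title": res.title}
        for cid in sorted(res.per_clinic):
            cc = res.per_clinic[cid]
            pct = cc.percentage()
            rec[f"{cid}_denominator"] = cc.denominator
            if not cc.available or pct is None:
                rec[f"{cid}_percentage"] = NOT_AVAILABLE
            else:
                rec[f"{cid}_percentage"] = round_half_up(pct, 1)
        pooled = res.pooled()
        rec["total_denominator"] = pooled.denominator
        pct = pooled.percentage()
        rec["total_percentage"] = NOT_AVAILABLE if pct is None else round_half_up(pct, 1)
        records.append(rec)
    return records


def render_report(results: list[IndicatorResult], fmt: str, path: str | Path) -> Path:
    """Write indicator results as CSV or JSON; the two renderings agree
    field for field."""
    path = Path(path)
    records = results_to_records(results)
    if fmt == "json":
        path.write_text(json.dumps(records, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    elif fmt == "csv":
        fields = list(records[0]) if records else ["indicator_id", "title"]
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=fields)
            writer.writeheader()
            writer.writerows(records)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
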