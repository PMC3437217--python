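"""Declarative quality-of-care indicator engine.

Each indicator is a denominator predicate (who is eligible) and a numerator
predicate (whose care met the criterion) over a cleaned
:class:`~diabeqc.cohort.PatientTimeline`. Evaluation yields a tri-state
outcome per patient and indicator: not in the denominator, denominator only,
or numerator. Rates are reported per clinic and pooled
(100 x sum-of-numerators / sum-of-denominators).

Conventions the catalog encodes:

* "in the last three visits" means the drug appears on at least one
  prescription dated at any of the patient's last three family-doctor visit
  dates inside the window;
* "in the last 3 measurements" evaluates over the last ``min(3, n)`` available
  cleaned measurements, with at least one required for eligibility;
* a contraindication to the indicated drug removes the patient from the
  denominator rather than counting as a failure;
* an undetermined measurement state (no relevant measurements at all) maps to
  "not in denominator".
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from importlib import resources
from typing import Callable, Sequence

import yaml

from .cohort import Cohort, PatientTimeline
from .model import Contraindication, Drug

ASA_DOSE_RANGE_MG = (75.0, 150.0)
CHOLESTEROL_TARGET_MG_DL = 200.0
HBA1C_TARGET_PCT = 7.0
GLUCOSE_TARGET_MG_DL = 130.0
BP_TARGET = (130.0, 80.0)
WEIGHT_LOSS_TARGET_PCT = -5.0


class Tristate(Enum):
    MET = "met"
    NOT_MET = "not_met"
    UNDETERMINED = "undetermined"


class OutcomeState(Enum):
    NOT_IN_DENOMINATOR = "not_in_denominator"
    DENOMINATOR_ONLY = "denominator_only"
    NUMERATOR = "numerator"


class NotProgrammableError(ValueError):
    """Raised when an inactive (discarded or free-text) indicator is evaluated."""


def last_k(series: Sequence, k: int) -> list:
    """The final ``min(k, len)`` elements of a date-sorted series."""
    if k <= 0:
        raise ValueError("k must be positive")
    return list(series[-k:])


def glycemic_control(timeline: PatientTimeline) -> Tristate:
    """Glycemic target: HbA1c < 7% or fasting glucose <= 130 mg/dl over the
    last 3 measurements; undetermined when neither analyte was measured."""
    hba1c = timeline.series.get("hba1c", [])
    glucose = timeline.series.get("fasting_glucose", [])
    if not hba1c and not glucose:
        return Tristate.UNDETERMINED
    ok_h = bool(hba1c) and all(v < HBA1C_TARGET_PCT for _, v in last_k(hba1c, 3))
    ok_g = bool(glucose) and all(v <= GLUCOSE_TARGET_MG_DL for _, v in last_k(glucose, 3))
    return Tristate.MET if (ok_h or ok_g) else Tristate.NOT_MET


def bp_control(timeline: PatientTimeline) -> Tristate:
    """Blood pressure < 130/80 mmHg in all of the last 3 measured pairs."""
    if not timeline.bp:
        return Tristate.UNDETERMINED
    ok = all(
        s < BP_TARGET[0] and d < BP_TARGET[1] for _, s, d in last_k(timeline.bp, 3)
    )
    return Tristate.MET if ok else Tristate.NOT_MET


def cholesterol_control(timeline: PatientTimeline) -> Tristate:
    """Total cholesterol < 200 mg/dl at the last in-window measurement."""
    chol = timeline.series.get("total_cholesterol", [])
    if not chol:
        return Tristate.UNDETERMINED
    return Tristate.MET if chol[-1][1] < CHOLESTEROL_TARGET_MG_DL else Tristate.NOT_MET


def weight_change_pct(timeline: PatientTimeline) -> float | None:
    """Relative weight change 100*(last-first)/first over in-window weights;
    None with fewer than two dated weights."""
    weights = timeline.series.get("weight_kg", [])
    if len(weights) < 2:
        return None
    first, last = weights[0][1], weights[-1][1]
    return 100.0 * (last - first) / first


def received_drug(
    timeline: PatientTimeline,
    drugs: frozenset[Drug],
    dose_range_mg: tuple[float, float] | None = None,
) -> bool:
    """Drug (optionally dose-restricted) prescribed at >= 1 of the last three
    family-doctor visits in the window."""
    for visit_date in last_k(timeline.visit_dates, 3):
        for drug, dose in timeline.prescriptions_by_date.get(visit_date, []):
            if drug not in drugs:
                continue
            if dose_range_mg is None:
                return True
            if dose is not None and dose_range_mg[0] <= dose <= dose_range_mg[1]:
                return True
    return False


# ---------------------------------------------------------------------------
# catalog


class Family(str, Enum):
    DETECTION = "detection"
    NON_PHARMACOLOGICAL = "non_pharmacological"
    PHARMACOLOGICAL = "pharmacological"
    OUTCOME = "outcome"


Predicate = Callable[[PatientTimeline], bool]


@dataclass(frozen=True)
class IndicatorDefinition:
    id: str
    title: str
    family: Family
    active: bool
    validity_mean: float
    feasibility_mean: float
    status: str  # accepted | discarded
    programmable: bool
    denominator: Predicate | None = None
    numerator: Predicate | None = None
    #: availability probe: a clinic where no cohort patient satisfies this is
    #: reported "Not available" (it still contributes its full denominator)
    availability_probe: Predicate | None = None


def _no_contra(timeline: PatientTimeline, which: Contraindication) -> bool:
    return which not in timeline.contraindications


def _den_all(t: PatientTimeline) -> bool:
    return True


def _den_p4(t: PatientTimeline) -> bool:
    return not t.dyslipidemia_before_window


def _num_p4(t: PatientTimeline) -> bool:
    return bool(t.series.get("total_cholesterol"))


def _den_p6(t: PatientTimeline) -> bool:
    return (
        t.bmi_first is not None
        and t.bmi_first[1] in ("overweight", "obese")
        and _no_contra(t, Contraindication.METFORMIN)
    )


def _den_p7(t: PatientTimeline) -> bool:
    return t.has_comorbidity("hypertension") and _no_contra(t, Contraindication.ACEI_ARB)


def _den_p8(t: PatientTimeline) -> bool:
    return (
        t.age_years > 40
        and any(t.has_comorbidity(c) for c in ("smoking", "hypertension", "dyslipidemia"))
        and _no_contra(t, Contraindication.ASA)
    )


def _den_p9(t: PatientTimeline) -> bool:
    chol = t.series.get("total_cholesterol", [])
    return (
        bool(chol)
        and chol[-1][1] > CHOLESTEROL_TARGET_MG_DL
        and _no_contra(t, Contraindication.STATIN)
    )


def _den_o1(t: PatientTimeline) -> bool:
    return glycemic_control(t) is not Tristate.UNDETERMINED


def _den_o2(t: PatientTimeline) -> bool:
    return cholesterol_control(t) is not Tristate.UNDETERMINED


def _den_o3(t: PatientTimeline) -> bool:
    return bp_control(t) is not Tristate.UNDETERMINED


def _den_o4(t: PatientTimeline) -> bool:
    return _den_p6(t) and len(t.series.get("weight_kg", [])) >= 2


def _den_o5(t: PatientTimeline) -> bool:
    return _den_o1(t) and _den_o2(t) and _den_o3(t)


def _num_o5(t: PatientTimeline) -> bool:
    return (
        glycemic_control(t) is Tristate.MET
        and cholesterol_control(t) is Tristate.MET
        and bp_control(t) is Tristate.MET
    )


RULES: dict[str, dict[str, Predicate]] = {
    "p1": {
        "denominator": _den_all,
        "numerator": lambda t: bool(t.series.get("hba1c")),
        "availability_probe": lambda t: bool(t.series.get("hba1c")),
    },
    "p2": {
        "denominator": _den_all,
        "numerator": lambda t: any(k.value == "foot_exam" for _, k in t.care_events),
    },
    "p3": {
        "denominator": _den_all,
        "numerator": lambda t: any(k.value == "ophthalmology_referral" for _, k in t.care_events),
    },
    "p4": {"denominator": _den_p4, "numerator": _num_p4},
    "p5": {"denominator": _den_all, "numerator": lambda t: bool(t.nutrition_visit_dates)},
    "p6": {
        "denominator": _den_p6,
        "numerator": lambda t: received_drug(t, frozenset({Drug.METFORMIN})),
    },
    "p7": {
        "denominator": _den_p7,
        "numerator": lambda t: received_drug(t, frozenset({Drug.ACEI, Drug.ARB})),
    },
    "p8": {
        "denominator": _den_p8,
        "numerator": lambda t: received_drug(
            t, frozenset({Drug.ACETYLSALICYLIC_ACID}), ASA_DOSE_RANGE_MG
        ),
    },
    "p9": {
        "denominator": _den_p9,
        "numerator": lambda t: received_drug(t, frozenset({Drug.STATIN})),
    },
    "o1": {"denominator": _den_o1, "numerator": lambda t: glycemic_control(t) is Tristate.MET},
    "o2": {"denominator": _den_o2, "numerator": lambda t: cholesterol_control(t) is Tristate.MET},
    "o3": {"denominator": _den_o3, "numerator": lambda t: bp_control(t) is Tristate.MET},
    "o4": {
        "denominator": _den_o4,
        "numerator": lambda t: (lambda c: c is not None and c <= WEIGHT_LOSS_TARGET_PCT)(
            weight_change_pct(t)
        ),
    },
    "o5": {"denominator": _den_o5, "numerator": _num_o5},
}


def load_catalog_metadata() -> list[dict]:
    """The packaged candidate-indicator catalog, in panel-review order."""
    text = resources.files("diabeqc.data").joinpath("indicator_catalog.yaml").read_text("utf-8")
    return yaml.safe_load(text)["candidates"]


def default_catalog() -> list[IndicatorDefinition]:
    """All 23 candidates; rule predicates bound for the 14 active indicators."""
    defs = []
    for entry in load_catalog_metadata():
        active = entry["status"] == "accepted" and entry["programmable"]
        rules = RULES.get(entry["id"], {}) if active else {}
        defs.append(
            IndicatorDefinition(
                id=entry["id"],
                title=entry["title"],
                family=Family(entry["family"]),
                active=active,
                validity_mean=float(entry["validity_mean"]),
                feasibility_mean=float(entry["feasibility_mean"]),
                status=entry["status"],
                programmable=bool(entry["programmable"]),
                denominator=rules.get("denominator"),
                numerator=rules.get("numerator"),
                availability_probe=rules.get("availability_probe"),
            )
        )
    ids = [d.id for d in defs]
    if len(ids) != len(set(ids)):
        raise ValueError("catalog ids must be unique")
    return defs


def active_catalog() -> list[IndicatorDefinition]:
    return [d for d in default_catalog() if d.active]


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class PatientIndicatorOutcome:
    patient_id: str
    indicator_id: str
    state: OutcomeState


@dataclass
class ClinicCount:
    numerator: int = 0
    denominator: int = 0
    available: bool = True

    def percentage(self) -> float | None:
        """Unrounded percentage; None on an empty denominator."""
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator


@dataclass
class IndicatorResult:
    indicator_id: str
    title: str
    per_clinic: dict[str, ClinicCount]

    def pooled(self) -> ClinicCount:
        num = sum(c.numerator for c in self.per_clinic.values())
        den = sum(c.denominator for c in self.per_clinic.values())
        return ClinicCount(numerator=num, denominator=den, available=True)


def evaluate_indicator(
    defn: IndicatorDefinition, timeline: PatientTimeline
) -> PatientIndicatorOutcome:
    """Tri-state outcome for one patient: the numerator rule is consulted only
    when the denominator rule holds."""
    if not defn.active:
        raise NotProgrammableError(f"indicator {defn.id!r} not programmable")
    if not defn.denominator(timeline):
        state = OutcomeState.NOT_IN_DENOMINATOR
    elif defn.numerator(timeline):
        state = OutcomeState.NUMERATOR
    else:
        state = OutcomeState.DENOMINATOR_ONLY
    return PatientIndicatorOutcome(timeline.patient_id, defn.id, state)


def evaluate_all(
    cohort: Cohort, catalog: list[IndicatorDefinition] | None = None
) -> list[IndicatorResult]:
    """Per-clinic and pooled counts for every active indicator in the catalog."""
    catalog = catalog if catalog is not None else default_catalog()
    active = [d for d in catalog if d.active]
    clinics = sorted({t.clinic_id for t in cohort.timelines})
    results = []
    for defn in active:
        counts = {cid: ClinicCount() for cid in clinics}
        probe_hits = {cid: False for cid in clinics}
        for t in cohort.timelines:
            outcome = evaluate_indicator(defn, t)
            cc = counts[t.clinic_id]
            if outcome.state is not OutcomeState.NOT_IN_DENOMINATOR:
                cc.denominator += 1
            if outcome.state is OutcomeState.NUMERATOR:
                cc.numerator += 1
            if defn.availability_probe is not None and defn.availability_probe(t):
                probe_hits[t.clinic_id] = True
        if defn.availability_probe is not None:
            for cid in clinics:
                counts[cid].available = probe_hits[cid]
        results.append(IndicatorResult(indicator_id=defn.id, title=defn.title, per_clinic=counts))
    return results


def evaluate_patients(
    cohort: Cohort, catalog: list[IndicatorDefinition] | None = None
) -> dict[tuple[str, str], OutcomeState]:
    """Per-(patient, indicator) tri-state map, for audits and ground-truth checks."""
    catalog = catalog if catalog is not None else default_catalog()
    out: dict[tuple[str, str], OutcomeState] = {}
    for defn in (d for d in catalog if d.active):
        for t in cohort.timelines:
            out[(t.patient_id, defn.id)] = evaluate_indicator(defn, t).state
    return out
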