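"""Cohort selection, plausibility filtering and per-patient timelines.

The analysis cohort is every patient carrying a type 2 diabetes ICD-10 code
(E11.1-E11.9, E14.0-E14.9 or E14.X) in any of the three diagnosis slots, aged
20 or more completed years at the start of the observation window, with at
least one family-doctor visit inside the window.

Measurements are screened against predefined biological plausibility bounds
(e.g. systolic pressure below 50 mmHg is a data error, not a reading); values
outside the retained range are excluded from every downstream computation and
recorded in a cleaning log. The bounds themselves are retained: exclusion is
strictly below the lower or strictly above the upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

from .model import (
    Analyte,
    CareEventKind,
    Contraindication,
    Drug,
    EHRBundle,
    Employment,
    InsuranceRole,
    LabStatus,
    MaritalStatus,
    PatientRecord,
    Schooling,
    Sex,
    VisitType,
)
from .util import completed_years, round_half_up


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# diagnosis-code logic


def normalize_icd10(code: str) -> str:
    """Uppercase and strip dots: ``e11.2`` -> ``E112``."""
    return code.strip().upper().replace(".", "")


def _default_t2dm_codes() -> frozenset[str]:
    codes = {f"E11{i}" for i in range(1, 10)}
    codes |= {f"E14{i}" for i in range(0, 10)}
    # E14X matches both the literal code and the bare stem, since coding
    # dialects differ on how an unspecified fourth character is written.
    codes |= {"E14X", "E14"}
    return frozenset(codes)


T2DM_CODES = _default_t2dm_codes()


@dataclass(frozen=True)
class CohortCriteria:
    icd10_codes: frozenset[str] = T2DM_CODES
    min_age_years: int = 20
    window_start: date = date(2009, 1, 1)
    window_end: date = date(2009, 12, 31)
    required_visit_type: VisitType = VisitType.FAMILY_DOCTOR

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ConfigError("window start must not be after window end")
        if not self.icd10_codes:
            raise ConfigError("code set must be non-empty")


def is_t2dm_code(code: str, criteria: CohortCriteria | None = None) -> bool:
    """True iff the (normalised) code is in the cohort's T2DM code set."""
    codes = (criteria or CohortCriteria()).icd10_codes
    return normalize_icd10(code) in codes


# comorbidity groups derived from diagnosis codes; the fourth character of the
# diabetes codes encodes the chronic complication
_COMPLICATION_BY_4TH = {
    "2": "nephropathy",
    "3": "retinopathy",
    "4": "neuropathy",
    "5": "peripheral_vascular",
}
_HYPERTENSION_PREFIXES = tuple(f"I1{i}" for i in range(0, 6))
_OTHER_CVD_PREFIXES = tuple(f"I2{i}" for i in range(0, 6)) + ("I50",)
_SMOKING_PREFIXES = ("F17", "Z720")

COMPLICATION_TYPES = ("peripheral_vascular", "nephropathy", "retinopathy", "neuropathy")


def comorbidity_groups(code: str) -> frozenset[str]:
    """Map one ICD-10 code to the comorbidity/complication groups it flags."""
    c = normalize_icd10(code)
    groups: set[str] = set()
    if c.startswith(_HYPERTENSION_PREFIXES):
        groups.add("hypertension")
    if c.startswith("E78"):
        groups.add("dyslipidemia")
    if c.startswith(_OTHER_CVD_PREFIXES):
        groups.add("other_cvd")
    if c.startswith(_SMOKING_PREFIXES):
        groups.add("smoking")
    if c.startswith(("E11", "E14")) and len(c) >= 4 and c[3] in _COMPLICATION_BY_4TH:
        groups.add(_COMPLICATION_BY_4TH[c[3]])
    # dedicated complication codes occasionally used instead of the stem
    if c.startswith("N08"):
        groups.add("nephropathy")
    if c.startswith("H360"):
        groups.add("retinopathy")
    if c.startswith("G632"):
        groups.add("neuropathy")
    if c.startswith("I73"):
        groups.add("peripheral_vascular")
    return frozenset(groups)


# ---------------------------------------------------------------------------
# plausibility


#: measure name -> (lower, upper) retained range; None means unbounded
DEFAULT_BOUNDS: dict[str, tuple[float | None, float | None]] = {
    "systolic": (50.0, 250.0),
    "diastolic": (40.0, 200.0),
    "height_cm": (130.0, 250.0),
    "weight_kg": (30.0, 200.0),
    "hba1c": (3.0, None),
    "fasting_glucose": (37.0, None),
    "total_cholesterol": (100.0, None),
}

#: lab analyte -> measure name used in the bounds table
ANALYTE_MEASURE = {
    Analyte.HBA1C: "hba1c",
    Analyte.FASTING_GLUCOSE: "fasting_glucose",
    Analyte.TOTAL_CHOLESTEROL: "total_cholesterol",
}


@dataclass(frozen=True)
class PlausibilityBounds:
    bounds: dict[str, tuple[float | None, float | None]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        for measure, (lo, hi) in self.bounds.items():
            if lo is not None and hi is not None and not lo < hi:
                raise ConfigError(f"bounds for {measure}: lower must be below upper")

    def range_for(self, measure: str) -> tuple[float | None, float | None]:
        try:
            return self.bounds[measure]
        except KeyError:
            raise ConfigError(f"no plausibility bounds defined for measure {measure!r}")


def plausible(measure: str, value: float, bounds: PlausibilityBounds | None = None) -> bool:
    """True iff the value lies inside the retained range (bounds inclusive)."""
    lo, hi = (bounds or PlausibilityBounds()).range_for(measure)
    if lo is not None and value < lo:
        return False
    if hi is not None and value > hi:
        return False
    return True


DatedValue = tuple[date, float]


def clean_measurements(
    series: list[DatedValue], measure: str, bounds: PlausibilityBounds | None = None
) -> tuple[list[DatedValue], list[dict]]:
    """Drop non-plausible values from a dated series.

    Returns the retained values sorted by date (stable for ties) and a log with
    one entry per removed value.
    """
    bounds = bounds or PlausibilityBounds()
    ordered = sorted(series, key=lambda dv: dv[0])
    kept: list[DatedValue] = []
    log: list[dict] = []
    for d, v in ordered:
        if plausible(measure, v, bounds):
            kept.append((d, v))
        else:
            log.append({"measure": measure, "date": d.isoformat(), "value": v, "issue": "implausible"})
    return kept, log


def dedupe_same_day(series: list[DatedValue]) -> tuple[list[DatedValue], list[dict]]:
    """Keep the last-loaded value per date (deterministic, auditable tie-break)."""
    by_date: dict[date, float] = {}
    log: list[dict] = []
    for d, v in series:
        if d in by_date:
            log.append({"date": d.isoformat(), "dropped_value": by_date[d], "issue": "same_day_duplicate"})
        by_date[d] = v
    return sorted(by_date.items()), log


# ---------------------------------------------------------------------------
# BMI


def compute_bmi(
    weight_kg: float | None, height_cm: float | None, bounds: PlausibilityBounds | None = None
) -> float | None:
    """Weight/height^2 in kg/m^2 to two decimals; None on missing or implausible input."""
    if weight_kg is None or height_cm is None:
        return None
    bounds = bounds or PlausibilityBounds()
    if not plausible("weight_kg", weight_kg, bounds) or not plausible("height_cm", height_cm, bounds):
        return None
    return round_half_up(weight_kg / (height_cm / 100.0) ** 2, 2)


BMI_CATEGORIES = ("underweight", "normal", "overweight", "obese")


def classify_bmi(bmi: float) -> str:
    """Half-open bins: <18.5, [18.5, 25), [25, 30), >=30."""
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


# ---------------------------------------------------------------------------
# timelines and cohort


BPPair = tuple[date, float, float]


@dataclass
class PatientTimeline:
    """One patient's date-ordered, plausibility-cleaned events in the window."""

    patient_id: str
    clinic_id: str
    age_years: int
    sex: Sex
    schooling: Schooling
    marital_status: MaritalStatus
    employment: Employment
    insurance_role: InsuranceRole
    diabetes_duration_years: int | None
    contraindications: frozenset[Contraindication]
    comorbidities: frozenset[str]  # hypertension, dyslipidemia, other_cvd, smoking
    complications: frozenset[str]  # subset of COMPLICATION_TYPES
    dyslipidemia_before_window: bool
    series: dict[str, list[DatedValue]]  # hba1c, fasting_glucose, total_cholesterol, weight_kg
    bp: list[BPPair]
    visit_dates: list[date]  # family-doctor visits, in-window, distinct, sorted
    nutrition_visit_dates: list[date]
    prescriptions_by_date: dict[date, list[tuple[Drug, float | None]]]
    care_events: list[tuple[date, CareEventKind]]
    bmi_first: tuple[float, str] | None
    bmi_last: tuple[float, str] | None
    cleaning_log: list[dict] = field(default_factory=list)

    def has_comorbidity(self, name: str) -> bool:
        return name in self.comorbidities

    def visit_count(self) -> int:
        return len(self.visit_dates)


@dataclass
class Cohort:
    criteria: CohortCriteria
    bounds: PlausibilityBounds
    timelines: list[PatientTimeline]
    exclusion_log: dict[str, str]  # patient_id -> reason, T2DM-coded patients only

    def by_clinic(self) -> dict[str, list[PatientTimeline]]:
        out: dict[str, list[PatientTimeline]] = {}
        for t in self.timelines:
            out.setdefault(t.clinic_id, []).append(t)
        return out

    def clinic_counts(self) -> dict[str, int]:
        return {cid: len(ts) for cid, ts in self.by_clinic().items()}

    def size(self) -> int:
        return len(self.timelines)


class _BundleIndex:
    """Per-patient record lookup, built once per bundle."""

    def __init__(self, bundle: EHRBundle) -> None:
        self.diagnoses: dict[str, list] = {}
        self.visits: dict[str, list] = {}
        self.vitals: dict[str, list] = {}
        self.prescriptions: dict[str, list] = {}
        self.labs: dict[str, list] = {}
        self.care_events: dict[str, list] = {}
        for d in bundle.diagnoses:
            self.diagnoses.setdefault(d.patient_id, []).append(d)
        for v in bundle.visits:
            self.visits.setdefault(v.patient_id, []).append(v)
        for v in bundle.vitals:
            self.vitals.setdefault(v.patient_id, []).append(v)
        for p in bundle.prescriptions:
            self.prescriptions.setdefault(p.patient_id, []).append(p)
        for l in bundle.labs:
            self.labs.setdefault(l.patient_id, []).append(l)
        for c in bundle.care_events:
            self.care_events.setdefault(c.patient_id, []).append(c)


def _age_at(patient: PatientRecord, on: date) -> int | None:
    if patient.birth_date is None:
        return None
    return completed_years(patient.birth_date, on)


def build_timeline(
    patient: PatientRecord,
    bundle: EHRBundle,
    criteria: CohortCriteria | None = None,
    bounds: PlausibilityBounds | None = None,
    _index: _BundleIndex | None = None,
) -> PatientTimeline:
    """Assemble a cleaned, windowed timeline for one patient.

    Diagnosis history is taken at any date up to the window end (comorbidities
    are medical history, with unlimited lookback); all other events are
    restricted to the window. Same-day duplicate measurements keep the
    last-loaded record, and the decision is logged.
    """
    criteria = criteria or CohortCriteria()
    bounds = bounds or PlausibilityBounds()
    idx = _index or _BundleIndex(bundle)
    ws, we = criteria.window_start, criteria.window_end
    pid = patient.patient_id
    log: list[dict] = []

    def logged(entries: list[dict]) -> None:
        for e in entries:
            log.append({"patient_id": pid, **e})

    # diagnosis-derived flags
    comorbidities: set[str] = set()
    complications: set[str] = set()
    dys_before = False
    for d in idx.diagnoses.get(pid, []):
        if d.recorded_date > we:
            continue
        groups = comorbidity_groups(d.icd10_code)
        comorbidities |= groups & {"hypertension", "dyslipidemia", "other_cvd", "smoking"}
        complications |= groups & set(COMPLICATION_TYPES)
        if "dyslipidemia" in groups and d.recorded_date < ws:
            dys_before = True

    # visits
    fam_dates = sorted(
        {
            v.visit_date
            for v in idx.visits.get(pid, [])
            if v.visit_type == criteria.required_visit_type and ws <= v.visit_date <= we
        }
    )
    nutrition_dates = sorted(
        {
            v.visit_date
            for v in idx.visits.get(pid, [])
            if v.visit_type == VisitType.NUTRITION_SERVICE and ws <= v.visit_date <= we
        }
    )

    # lab series, window-only, resulted only, cleaned
    series: dict[str, list[DatedValue]] = {}
    for analyte, measure in ANALYTE_MEASURE.items():
        raw = [
            (l.event_date, l.value)
            for l in idx.labs.get(pid, [])
            if l.analyte == analyte and l.status == LabStatus.RESULTED and ws <= l.event_date <= we
        ]
        cleaned, clog = clean_measurements(raw, measure, bounds)
        logged(clog)
        deduped, dlog = dedupe_same_day(cleaned)
        logged(dlog)
        series[measure] = deduped

    # vitals: per-measure series plus blood-pressure pairs
    in_window_vitals = [v for v in idx.vitals.get(pid, []) if ws <= v.measure_date <= we]
    for measure, attr in (("weight_kg", "weight_kg"), ("height_cm", "height_cm")):
        raw = [(v.measure_date, getattr(v, attr)) for v in in_window_vitals if getattr(v, attr) is not None]
        cleaned, clog = clean_measurements(raw, measure, bounds)
        logged(clog)
        deduped, dlog = dedupe_same_day(cleaned)
        logged(dlog)
        series[measure] = deduped

    # a BP pair needs both components present and plausible on the same record
    bp_by_date: dict[date, tuple[float, float]] = {}
    for v in in_window_vitals:
        if v.systolic_mmhg is None or v.diastolic_mmhg is None:
            continue
        ok_s = plausible("systolic", v.systolic_mmhg, bounds)
        ok_d = plausible("diastolic", v.diastolic_mmhg, bounds)
        if not (ok_s and ok_d):
            log.append(
                {
                    "patient_id": pid,
                    "measure": "blood_pressure",
                    "date": v.measure_date.isoformat(),
                    "value": [v.systolic_mmhg, v.diastolic_mmhg],
                    "issue": "implausible",
                }
            )
            continue
        if v.measure_date in bp_by_date:
            log.append(
                {
                    "patient_id": pid,
                    "measure": "blood_pressure",
                    "date": v.measure_date.isoformat(),
                    "issue": "same_day_duplicate",
                }
            )
        bp_by_date[v.measure_date] = (v.systolic_mmhg, v.diastolic_mmhg)
    bp = [(d, s, dd) for d, (s, dd) in sorted(bp_by_date.items())]

    # BMI at the earliest/latest in-window date with both components plausible
    bmi_dates: dict[date, tuple[float, float]] = {}
    for v in in_window_vitals:  # file order: later-loaded same-day record wins
        if v.weight_kg is None or v.height_cm is None:
            continue
        if plausible("weight_kg", v.weight_kg, bounds) and plausible("height_cm", v.height_cm, bounds):
            bmi_dates[v.measure_date] = (v.weight_kg, v.height_cm)

    def bmi_at(d: date) -> tuple[float, str]:
        w, h = bmi_dates[d]
        b = compute_bmi(w, h, bounds)
        return (b, classify_bmi(b))

    bmi_first = bmi_at(min(bmi_dates)) if bmi_dates else None
    bmi_last = bmi_at(max(bmi_dates)) if bmi_dates else None

    # prescriptions, grouped by visit date, in-window, file order preserved
    rx_by_date: dict[date, list[tuple[Drug, float | None]]] = {}
    for rx in idx.prescriptions.get(pid, []):
        if ws <= rx.visit_date <= we:
            rx_by_date.setdefault(rx.visit_date, []).append((rx.drug, rx.daily_dose_mg))

    care = sorted(
        (c.event_date, c.kind) for c in idx.care_events.get(pid, []) if ws <= c.event_date <= we
    )

    onset = patient.diabetes_onset_year
    duration = None
    if onset is not None and onset <= ws.year:
        duration = ws.year - onset

    return PatientTimeline(
        patient_id=pid,
        clinic_id=patient.clinic_id,
        age_years=_age_at(patient, ws) if patient.birth_date else -1,
        sex=patient.sex,
        schooling=patient.schooling,
        marital_status=patient.marital_status,
        employment=patient.employment,
        insurance_role=patient.insurance_role,
        diabetes_duration_years=duration,
        contraindications=patient.contraindications,
        comorbidities=frozenset(comorbidities),
        complications=frozenset(complications),
        dyslipidemia_before_window=dys_before,
        series=series,
        bp=bp,
        visit_dates=fam_dates,
        nutrition_visit_dates=nutrition_dates,
        prescriptions_by_date=rx_by_date,
        care_events=care,
        bmi_first=bmi_first,
        bmi_last=bmi_last,
        cleaning_log=log,
    )


def select_cohort(
    bundle: EHRBundle,
    criteria: CohortCriteria | None = None,
    bounds: PlausibilityBounds | None = None,
) -> Cohort:
    """Apply the three eligibility criteria and build cleaned timelines.

    A patient enters the cohort iff (a) any diagnosis record in any slot
    carries a matching T2DM code (at any date up to the window end), (b) age at
    window start is at least ``min_age_years`` completed years, and (c) there
    is at least one qualifying visit inside the window. Every T2DM-coded
    patient who fails (b) or (c) appears in the exclusion log with one reason.
    """
    criteria = criteria or CohortCriteria()
    bounds = bounds or PlausibilityBounds()
    idx = _BundleIndex(bundle)
    ws, we = criteria.window_start, criteria.window_end

    timelines: list[PatientTimeline] = []
    exclusions: dict[str, str] = {}
    for patient in bundle.patients:
        pid = patient.patient_id
        has_code = any(
            is_t2dm_code(d.icd10_code, criteria)
            for d in idx.diagnoses.get(pid, [])
            if d.recorded_date <= we
        )
        if not has_code:
            continue
        age = _age_at(patient, ws)
        if age is None or age < criteria.min_age_years:
            exclusions[pid] = "age"
            continue
        has_visit = any(
            v.visit_type == criteria.required_visit_type and ws <= v.visit_date <= we
            for v in idx.visits.get(pid, [])
        )
        if not has_visit:
            exclusions[pid] = "no visit in window"
            continue
        timelines.append(build_timeline(patient, bundle, criteria, bounds, _index=idx))

    return Cohort(criteria=criteria, bounds=bounds, timelines=timelines, exclusion_log=exclusions)
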