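"""Synthetic multi-clinic primary-care EHR generator.

Emulates the statistical structure the downstream analysis assumes: a set of
family-medicine clinics whose adult attendees include ~14.4% patients with a
type 2 diabetes diagnosis; T2DM patients carry realistic demographics
(age ~ N(62.3, 12.9), 58.5% female), comorbidity prevalences (hypertension
60.4%, dyslipidemia 41.6%, other cardiovascular disease 9.2%, chronic
complication 31.7%), a negative-binomial visit count (mean 8.8, sd 4.6), BMI
categories skewed toward overweight/obesity, and laboratory capacity that may
lack HbA1c in some clinics.

Generation is eligibility-then-adherence: a patient's eligibility attributes
(BMI category, comorbidities, contraindications, measured labs) are drawn
first, then each indicator's numerator event is emitted with the configured
per-indicator adherence probability conditional on eligibility. The generator
records the ground truth (per-patient eligibility and numerator flags) in a
sidecar, so the cohort builder and indicator engine can be checked against it
exactly.

Data-quality defects (field-level missingness, biologically implausible
vitals) are injected by a separate, explicit step whose injected positions are
logged; injected values lie strictly outside the plausibility bounds, so the
cleaning stage removes exactly the injected set.

Identical seeds yield byte-identical bundles.
"""

from __future__ import annotations

import copy
import json
import string
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np

from .cohort import ConfigError
from .model import (
    Analyte,
    CareEventKind,
    CareEventRecord,
    Contraindication,
    DiagnosisRecord,
    Drug,
    EHRBundle,
    Employment,
    InsuranceRole,
    LabRecord,
    LabStatus,
    MaritalStatus,
    PatientRecord,
    PrescriptionRecord,
    Schooling,
    Sex,
    VisitRecord,
    VisitType,
    VitalRecord,
)

ACTIVE_INDICATOR_IDS = ("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8", "p9", "o1", "o2", "o3", "o4", "o5")


def _default_adherence() -> dict[str, float]:
    # per-indicator probability that an eligible patient meets the numerator;
    # defaults follow the pooled rates observed in the four-clinic study
    return {
        "p1": 0.13,  # per clinic with HbA1c capacity
        "p2": 0.303,
        "p3": 0.130,
        "p4": 0.578,
        "p5": 0.039,
        "p6": 0.632,
        "p7": 0.574,
        "p8": 0.434,
        "p9": 0.479,
        "o1": 0.231,
        "o2": 0.520,
        "o3": 0.108,
        "o4": 0.133,
    }


@dataclass
class SimulationConfig:
    n_clinics: int = 4
    members_per_clinic: int = 3000
    attendance_probability: float = 0.30
    t2dm_prevalence_among_attendees: float = 0.144
    observation_year: int = 2009
    age_mean: float = 62.3
    age_sd: float = 12.9
    female_fraction: float = 0.585
    comorbidity_prevalences: dict[str, float] = field(
        default_factory=lambda: {
            "hypertension": 0.604,
            "dyslipidemia": 0.416,
            "other_cvd": 0.092,
            "chronic_complication": 0.317,
        }
    )
    smoking_prevalence: float = 0.10
    visits_per_year_mean: float = 8.8
    visits_per_year_sd: float = 4.6
    bmi_category_probabilities: dict[str, float] = field(
        default_factory=lambda: {"under": 0.004, "normal": 0.183, "over": 0.419, "obese": 0.394}
    )
    schooling_probabilities: dict[str, float] = field(
        default_factory=lambda: {
            "illiterate": 0.174,
            "primary": 0.376,
            "secondary": 0.172,
            "high_school": 0.178,
            "university": 0.100,
        }
    )
    marital_probabilities: dict[str, float] = field(
        default_factory=lambda: {"married_partner": 0.670, "single_divorced": 0.141, "widowed": 0.189}
    )
    employment_probabilities: dict[str, float] = field(
        default_factory=lambda: {
            "housewife": 0.510,
            "employed": 0.305,
            "unemployed": 0.004,
            "retired": 0.181,
        }
    )
    insurance_subscriber_fraction: float = 0.233
    duration_band_probabilities: dict[str, float] = field(
        default_factory=lambda: {"lt5": 0.068, "5_10": 0.239, "11_15": 0.223, "gt15": 0.470}
    )
    glucose_measured_probability: float = 0.55
    ordered_only_probability: float = 0.35
    contraindication_probability: float = 0.0
    missingness_rates: dict[str, float] = field(
        default_factory=lambda: {
            "schooling": 0.287,
            "marital_status": 0.310,
            "employment": 0.426,
            "diabetes_duration": 0.645,
            "bmi": 0.143,
        }
    )
    implausible_rates: dict[str, float] = field(
        default_factory=lambda: {
            "weight_kg": 0.09,
            "height_cm": 0.05,
            "systolic": 0.18,
            "diastolic": 0.24,
        }
    )
    indicator_adherence: dict[str, float] = field(default_factory=_default_adherence)
    #: per-clinic HbA1c laboratory capacity; None -> first two clinics only,
    #: emulating a system where half the sites lack the assay
    hba1c_available_by_clinic: tuple[bool, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        probs = [
            self.attendance_probability,
            self.t2dm_prevalence_among_attendees,
            self.female_fraction,
            self.glucose_measured_probability,
            self.ordered_only_probability,
            self.contraindication_probability,
            self.insurance_subscriber_fraction,
            self.smoking_prevalence,
            *self.comorbidity_prevalences.values(),
            *self.bmi_category_probabilities.values(),
            *self.missingness_rates.values(),
            *self.implausible_rates.values(),
            *self.indicator_adherence.values(),
        ]
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability out of [0, 1]: {p}")
        if self.n_clinics < 1 or self.members_per_clinic < 0:
            raise ConfigError("n_clinics must be >= 1 and members_per_clinic >= 0")

    def hba1c_availability(self) -> tuple[bool, ...]:
        if self.hba1c_available_by_clinic is not None:
            if len(self.hba1c_available_by_clinic) != self.n_clinics:
                raise ConfigError("hba1c_available_by_clinic must list one flag per clinic")
            return tuple(self.hba1c_available_by_clinic)
        return tuple(i < 2 for i in range(self.n_clinics))


def clinic_ids(config: SimulationConfig) -> list[str]:
    letters = string.ascii_uppercase
    return [
        f"FMC_{letters[i]}" if i < len(letters) else f"FMC_{i + 1}"
        for i in range(config.n_clinics)
    ]


@dataclass
class SimulationResult:
    bundle: EHRBundle
    #: patient_id -> indicator_id -> {"eligible": bool, "numerator": bool};
    #: entries exist for every generated T2DM patient
    truth: dict[str, dict[str, dict[str, bool]]]


# ---------------------------------------------------------------------------
# helpers


_BMI_BANDS = {
    # margins inside each category keep rounding of stored weight/height from
    # flipping the recomputed category at a band edge
    "under": (16.0, 18.2),
    "normal": (18.7, 24.7),
    "over": (25.2, 29.7),
    "obese": (30.3, 39.5),
}

_DURATION_BANDS = {"lt5": (1, 4), "5_10": (5, 10), "11_15": (11, 15), "gt15": (16, 30)}

_COMPLICATION_CODE = {
    "nephropathy": "E112",
    "retinopathy": "E113",
    "neuropathy": "E114",
    "peripheral_vascular": "E115",
}

# relative frequencies of complication subtypes among patients with any
_COMPLICATION_WEIGHTS = {
    "peripheral_vascular": 0.145,
    "nephropathy": 0.106,
    "retinopathy": 0.079,
    "neuropathy": 0.049,
}


def _days_in_year(year: int) -> int:
    return (date(year + 1, 1, 1) - date(year, 1, 1)).days


def _choice(rng: np.random.Generator, options: dict[str, float]) -> str:
    keys = list(options)
    probs = np.array([options[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _birth_date_for_age(rng: np.random.Generator, age: int, year: int) -> date:
    # born after 1 Jan so that completed years at the window start equal `age`
    month = int(rng.integers(2, 13))
    day = int(rng.integers(1, 29))
    return date(year - age - 1, month, day)


def _visit_count(rng: np.random.Generator, mean: float, sd: float) -> int:
    var = sd * sd
    if var <= mean:  # Poisson-like or underdispersed: fall back to Poisson
        n = int(rng.poisson(mean))
    else:
        r = mean * mean / (var - mean)  # negative-binomial dispersion
        p = r / (r + mean)
        n = int(rng.negative_binomial(r, p))
    return max(1, min(n, 60))


def _visit_dates(rng: np.random.Generator, n: int, year: int) -> list[date]:
    days = rng.choice(_days_in_year(year), size=min(n, _days_in_year(year)), replace=False)
    base = date(year, 1, 1)
    return sorted(base + timedelta(days=int(d)) for d in np.sort(days))


def _date_in(rng: np.random.Generator, start: date, end: date) -> date:
    span = (end - start).days
    return start + timedelta(days=int(rng.integers(0, span + 1)))


# ---------------------------------------------------------------------------
# patient-level generation


def generate_patient_history(
    patient: PatientRecord,
    config: SimulationConfig,
    rng: np.random.Generator,
    hba1c_available: bool = True,
) -> tuple[EHRBundle, dict[str, dict[str, bool]]]:
    """Records for one T2DM patient plus their ground-truth indicator flags.

    The returned bundle fragment holds only this patient's diagnosis, visit,
    vitals, prescription, lab and care-event records (not the patient row).
    """
    year = config.observation_year
    ws, we = date(year, 1, 1), date(year, 12, 31)
    adherence = config.indicator_adherence
    pid = patient.patient_id
    cid = patient.clinic_id
    age = (ws.year - patient.birth_date.year) - (
        (ws.month, ws.day) < (patient.birth_date.month, patient.birth_date.day)
    )
    frag = EHRBundle()

    # ---- latent eligibility attributes --------------------------------
    comorb = config.comorbidity_prevalences
    has_htn = rng.random() < comorb["hypertension"]
    has_dys = rng.random() < comorb["dyslipidemia"]
    has_cvd = rng.random() < comorb["other_cvd"]
    has_complication = rng.random() < comorb["chronic_complication"]
    smokes = rng.random() < config.smoking_prevalence
    complication = _choice(rng, _COMPLICATION_WEIGHTS) if has_complication else None
    bmi_cat = _choice(rng, config.bmi_category_probabilities)
    contra = patient.contraindications

    n_visits = _visit_count(rng, config.visits_per_year_mean, config.visits_per_year_sd)
    visits = _visit_dates(rng, n_visits, year)
    n_visits = len(visits)
    last3 = set(visits[-3:])
    for d in visits:
        frag.visits.append(VisitRecord(pid, cid, d, VisitType.FAMILY_DOCTOR))

    # ---- diagnoses -----------------------------------------------------
    def dx(code: str, when: date) -> None:
        if rng.random() < 0.25:  # exercise dot-normalisation downstream
            code = f"{code[:3]}.{code[3:]}" if len(code) > 3 else code
        frag.diagnoses.append(DiagnosisRecord(pid, code, when, int(rng.integers(1, 4))))

    t2dm_code = (
        _COMPLICATION_CODE[complication]
        if complication
        else str(rng.choice(["E119", "E14X", "E149"], p=[0.7, 0.2, 0.1]))
    )
    dx(t2dm_code, _date_in(rng, ws - timedelta(days=4 * 365), we))
    if has_htn:
        dx("I10", _date_in(rng, ws - timedelta(days=4 * 365), we))
    if has_dys:  # dated before the window so screening eligibility is exact
        dx("E780", _date_in(rng, ws - timedelta(days=4 * 365), ws - timedelta(days=1)))
    if has_cvd:
        dx("I251", _date_in(rng, ws - timedelta(days=4 * 365), we))
    if smokes:
        dx("F171", _date_in(rng, ws - timedelta(days=4 * 365), we))

    # ---- vitals ---------------------------------------------------------
    sex_shift = -6.0 if patient.sex is Sex.FEMALE else 6.0
    height = float(np.clip(rng.normal(162.0 + sex_shift, 6.0), 140.0, 195.0))
    height = round(height, 1)
    lo, hi = _BMI_BANDS[bmi_cat]
    bmi0 = float(rng.uniform(lo, hi))
    w0 = float(np.clip(bmi0 * (height / 100.0) ** 2, 31.0, 199.0))

    elig_o4 = bmi_cat in ("over", "obese") and Contraindication.METFORMIN not in contra and n_visits >= 2
    if elig_o4:
        loses = rng.random() < adherence["o4"]
        factor = float(rng.uniform(0.88, 0.949)) if loses else float(rng.uniform(0.965, 1.07))
    else:
        loses = False
        factor = float(rng.uniform(0.96, 1.06))
    w_last = float(np.clip(w0 * factor, 30.5, 199.0))

    bp_ok = rng.random() < adherence["o3"]  # all visits have a BP pair
    weights = np.linspace(w0, w_last, n_visits)
    if n_visits > 2:  # jitter interior weights only; endpoints carry the signal
        weights[1:-1] += rng.uniform(-0.4, 0.4, size=n_visits - 2)
    weights = np.clip(weights, 30.5, 199.0)
    for i, d in enumerate(visits):
        if bp_ok:
            sys_v = int(rng.integers(100, 129))
            dia_v = int(rng.integers(60, 79))
        else:
            if d in last3 and d == visits[-1]:
                sys_v = int(rng.integers(135, 166))  # force failure in last 3
                dia_v = int(rng.integers(70, 96))
            else:
                sys_v = int(rng.integers(110, 151))
                dia_v = int(rng.integers(65, 96))
        frag.vitals.append(
            VitalRecord(
                pid,
                d,
                weight_kg=round(float(weights[i]), 1),
                height_cm=height,
                systolic_mmhg=float(sys_v),
                diastolic_mmhg=float(dia_v),
            )
        )

    # ---- laboratory -----------------------------------------------------
    measured_h = hba1c_available and rng.random() < adherence["p1"]
    measured_g = rng.random() < config.glucose_measured_probability
    measured_c = rng.random() < adherence["p4"]

    glyc_ok = rng.random() < adherence["o1"] if (measured_h or measured_g) else False
    chol_ok = rng.random() < adherence["o2"] if measured_c else False

    def lab_dates(k: int) -> list[date]:
        k = min(k, n_visits)
        idx = rng.choice(n_visits, size=k, replace=False)
        return sorted(visits[i] for i in np.sort(idx))

    if measured_h:
        dates = lab_dates(int(rng.integers(1, 4)))
        for i, d in enumerate(dates):
            if glyc_ok:
                v = float(rng.uniform(5.5, 6.9))
            elif i == len(dates) - 1:
                v = float(rng.uniform(7.5, 11.0))  # last value out of target
            else:
                v = float(rng.uniform(6.0, 9.5))
            frag.labs.append(LabRecord(pid, d, Analyte.HBA1C, LabStatus.RESULTED, round(v, 1)))
    if measured_g:
        dates = lab_dates(int(rng.integers(1, 5)))
        for i, d in enumerate(dates):
            if glyc_ok:
                v = float(rng.uniform(80.0, 129.0))
            elif i == len(dates) - 1:
                v = float(rng.uniform(140.0, 260.0))
            else:
                v = float(rng.uniform(100.0, 220.0))
            frag.labs.append(LabRecord(pid, d, Analyte.FASTING_GLUCOSE, LabStatus.RESULTED, round(v, 1)))
    if measured_c:
        dates = lab_dates(int(rng.integers(1, 3)))
        for i, d in enumerate(dates):
            if i == len(dates) - 1:
                v = float(rng.uniform(130.0, 198.0)) if chol_ok else float(rng.uniform(205.0, 310.0))
            else:
                v = float(rng.uniform(150.0, 280.0))
            frag.labs.append(
                LabRecord(pid, d, Analyte.TOTAL_CHOLESTEROL, LabStatus.RESULTED, round(v, 1))
            )
    else:
        # orders placed but never drawn: registered order without a result
        if rng.random() < config.ordered_only_probability:
            frag.labs.append(
                LabRecord(pid, visits[int(rng.integers(0, n_visits))], Analyte.TOTAL_CHOLESTEROL, LabStatus.ORDERED_ONLY)
            )
        if not measured_g and rng.random() < config.ordered_only_probability:
            frag.labs.append(
                LabRecord(pid, visits[int(rng.integers(0, n_visits))], Analyte.FASTING_GLUCOSE, LabStatus.ORDERED_ONLY)
            )

    # ---- eligibility + adherence for the remaining indicators ----------
    elig = {
        "p1": True,
        "p2": True,
        "p3": True,
        "p4": not has_dys,
        "p5": True,
        "p6": bmi_cat in ("over", "obese") and Contraindication.METFORMIN not in contra,
        "p7": has_htn and Contraindication.ACEI_ARB not in contra,
        "p8": age > 40 and (smokes or has_htn or has_dys) and Contraindication.ASA not in contra,
        "p9": measured_c and not chol_ok and Contraindication.STATIN not in contra,
        "o1": measured_h or measured_g,
        "o2": measured_c,
        "o3": True,
        "o4": elig_o4,
    }
    num = {
        "p1": measured_h,
        "p4": elig["p4"] and measured_c,
        "o1": elig["o1"] and glyc_ok,
        "o2": elig["o2"] and chol_ok,
        "o3": bp_ok,
        "o4": elig["o4"] and loses,
    }

    def rx(drug: Drug, when: date, dose: float | None) -> None:
        frag.prescriptions.append(PrescriptionRecord(pid, when, drug, dose))

    def random_visit() -> date:
        return visits[int(rng.integers(0, n_visits))]

    # process indicators with care events / nutrition visits
    num["p2"] = rng.random() < adherence["p2"]
    if num["p2"]:
        frag.care_events.append(CareEventRecord(pid, random_visit(), CareEventKind.FOOT_EXAM))
    num["p3"] = rng.random() < adherence["p3"]
    if num["p3"]:
        frag.care_events.append(
            CareEventRecord(pid, random_visit(), CareEventKind.OPHTHALMOLOGY_REFERRAL)
        )
    num["p5"] = rng.random() < adherence["p5"]
    if num["p5"]:
        frag.visits.append(VisitRecord(pid, cid, _date_in(rng, ws, we), VisitType.NUTRITION_SERVICE))

    # pharmacological indicators: drug at one of the last three visits iff
    # adherent; non-adherent eligible patients get none there
    num["p6"] = elig["p6"] and rng.random() < adherence["p6"]
    if num["p6"]:
        rx(Drug.METFORMIN, visits[-1], 1700.0)
    elif not elig["p6"] and rng.random() < 0.5:
        rx(Drug.METFORMIN, random_visit(), 1700.0)

    num["p7"] = elig["p7"] and rng.random() < adherence["p7"]
    if num["p7"]:
        rx(Drug.ARB if rng.random() < 0.3 else Drug.ACEI, visits[-1], 20.0)

    num["p8"] = elig["p8"] and rng.random() < adherence["p8"]
    if num["p8"]:
        rx(Drug.ACETYLSALICYLIC_ACID, visits[-1], float(rng.choice([75.0, 100.0, 150.0], p=[0.15, 0.7, 0.15])))
    elif elig["p8"] and rng.random() < 0.25:
        rx(Drug.ACETYLSALICYLIC_ACID, visits[-1], 300.0)  # wrong dose, not credited

    num["p9"] = elig["p9"] and rng.random() < adherence["p9"]
    if num["p9"]:
        rx(Drug.STATIN, visits[-1], 20.0)

    # background hypoglycemics that no indicator tests
    if rng.random() < 0.45:
        rx(Drug.GLIBENCLAMIDE, random_visit(), 5.0)
    if rng.random() < 0.137:
        rx(Drug.INSULIN, random_visit(), None)

    elig["o5"] = elig["o1"] and elig["o2"] and elig["o3"]
    num["o5"] = elig["o5"] and num["o1"] and num["o2"] and num["o3"]

    truth = {
        ind: {"eligible": bool(elig[ind]), "numerator": bool(elig[ind] and num.get(ind, False))}
        for ind in ACTIVE_INDICATOR_IDS
    }
    return frag, truth


def _generate_patient_record(
    rng: np.random.Generator, pid: str, cid: str, config: SimulationConfig, t2dm: bool
) -> PatientRecord:
    year = config.observation_year
    if t2dm:
        age = int(np.clip(round(rng.normal(config.age_mean, config.age_sd)), 21, 99))
    else:
        age = int(rng.integers(20, 90))
    sex = Sex.FEMALE if rng.random() < config.female_fraction else Sex.MALE
    contra: set[Contraindication] = set()
    if t2dm and config.contraindication_probability > 0:
        for c in Contraindication:
            if rng.random() < config.contraindication_probability:
                contra.add(c)
    onset = None
    if t2dm:
        band = _choice(rng, config.duration_band_probabilities)
        d_lo, d_hi = _DURATION_BANDS[band]
        duration = int(rng.integers(d_lo, d_hi + 1))
        onset = max(year - duration, year - age + 15)
    return PatientRecord(
        patient_id=pid,
        clinic_id=cid,
        sex=sex,
        birth_date=_birth_date_for_age(rng, age, year),
        schooling=Schooling(_choice(rng, config.schooling_probabilities)),
        marital_status=MaritalStatus(_choice(rng, config.marital_probabilities)),
        employment=Employment(_choice(rng, config.employment_probabilities)),
        insurance_role=(
            InsuranceRole.SUBSCRIBER
            if rng.random() < config.insurance_subscriber_fraction
            else InsuranceRole.DEPENDENT
        ),
        diabetes_onset_year=onset,
        contraindications=frozenset(contra),
    )


def _extend(bundle: EHRBundle, frag: EHRBundle) -> None:
    bundle.diagnoses.extend(frag.diagnoses)
    bundle.visits.extend(frag.visits)
    bundle.vitals.extend(frag.vitals)
    bundle.prescriptions.extend(frag.prescriptions)
    bundle.labs.extend(frag.labs)
    bundle.care_events.extend(frag.care_events)


def simulate_with_truth(config: SimulationConfig) -> SimulationResult:
    """Generate the full multi-clinic bundle and the ground-truth sidecar."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    year = config.observation_year
    ws, we = date(year, 1, 1), date(year, 12, 31)
    bundle = EHRBundle(clinic_registry={})
    truth: dict[str, dict[str, dict[str, bool]]] = {}
    availability = config.hba1c_availability()

    for ci, cid in enumerate(clinic_ids(config)):
        n_attendees = (
            int(rng.binomial(config.members_per_clinic, config.attendance_probability))
            if config.members_per_clinic
            else 0
        )
        bundle.clinic_registry[cid] = {
            "members": config.members_per_clinic,
            "attendees": n_attendees,
        }
        for j in range(n_attendees):
            pid = f"{cid}-{j:06d}"
            is_t2dm = rng.random() < config.t2dm_prevalence_among_attendees
            patient = _generate_patient_record(rng, pid, cid, config, is_t2dm)
            bundle.patients.append(patient)
            if is_t2dm:
                frag, patient_truth = generate_patient_history(
                    patient, config, rng, hba1c_available=availability[ci]
                )
                _extend(bundle, frag)
                truth[pid] = patient_truth
            else:
                # background attendee: a couple of visits, occasional
                # hypertension history, no labs or vitals
                n = int(rng.integers(1, 4))
                for d in _visit_dates(rng, n, year):
                    bundle.visits.append(VisitRecord(pid, cid, d, VisitType.FAMILY_DOCTOR))
                if rng.random() < 0.3:
                    bundle.diagnoses.append(
                        DiagnosisRecord(
                            pid, "I10", _date_in(rng, ws - timedelta(days=4 * 365), we), 1
                        )
                    )
    return SimulationResult(bundle=bundle, truth=truth)


def generate_population(config: SimulationConfig) -> EHRBundle:
    """The generated bundle alone (see :func:`simulate_with_truth`)."""
    return simulate_with_truth(config).bundle


def write_truth_sidecar(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# data-quality defects


@dataclass
class DefectLog:
    missing: list[dict] = field(default_factory=list)
    implausible: list[dict] = field(default_factory=list)

    def implausible_by_measure(self) -> dict[str, set[tuple[str, str, float]]]:
        out: dict[str, set[tuple[str, str, float]]] = {}
        for e in self.implausible:
            out.setdefault(e["measure"], set()).add((e["patient_id"], e["date"], e["injected"]))
        return out


_VITAL_FIELD_BY_MEASURE = {
    "weight_kg": "weight_kg",
    "height_cm": "height_cm",
    "systolic": "systolic_mmhg",
    "diastolic": "diastolic_mmhg",
}

# (low_range, high_range): injected values fall strictly outside the retained
# plausibility interval, with margin so storage rounding cannot re-enter it
_IMPLAUSIBLE_RANGES = {
    "weight_kg": ((3.0, 29.0), (202.0, 400.0)),
    "height_cm": ((60.0, 129.0), (252.0, 320.0)),
    "systolic": ((10.0, 49.0), (252.0, 400.0)),
    "diastolic": ((5.0, 39.0), (202.0, 300.0)),
    "hba1c": ((0.3, 2.8), None),
    "fasting_glucose": ((2.0, 35.0), None),
    "total_cholesterol": ((10.0, 95.0), None),
}

_LAB_MEASURE_BY_ANALYTE = {
    Analyte.HBA1C: "hba1c",
    Analyte.FASTING_GLUCOSE: "fasting_glucose",
    Analyte.TOTAL_CHOLESTEROL: "total_cholesterol",
}


def _draw_implausible(rng: np.random.Generator, measure: str) -> float:
    low, high = _IMPLAUSIBLE_RANGES[measure]
    rng_range = low if (high is None or rng.random() < 0.7) else high
    return round(float(rng.uniform(*rng_range)), 1)


def inject_data_defects(
    bundle: EHRBundle, config: SimulationConfig
) -> tuple[EHRBundle, DefectLog]:
    """Return a defected copy of the bundle plus the defect log.

    Field-level missingness (schooling, marital status, employment, diabetes
    duration, BMI components) is applied at the configured per-field rates;
    targeted measurements are replaced by values strictly outside the
    plausibility bounds at the configured per-measure rates. Record counts are
    never altered, only field values; a vitals record always keeps at least
    one non-missing measurement.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1001])
    log = DefectLog()
    out = copy.copy(bundle)
    rates = config.missingness_rates

    patients = []
    for p in bundle.patients:
        changes = {}
        if p.schooling is not Schooling.MISSING and rng.random() < rates.get("schooling", 0.0):
            changes["schooling"] = Schooling.MISSING
        if p.marital_status is not MaritalStatus.MISSING and rng.random() < rates.get("marital_status", 0.0):
            changes["marital_status"] = MaritalStatus.MISSING
        if p.employment is not Employment.MISSING and rng.random() < rates.get("employment", 0.0):
            changes["employment"] = Employment.MISSING
        if p.diabetes_onset_year is not None and rng.random() < rates.get("diabetes_duration", 0.0):
            changes["diabetes_onset_year"] = None
        if changes:
            for fieldname in changes:
                log.missing.append({"table": "patients", "patient_id": p.patient_id, "field": fieldname})
            p = replace(p, **changes)
        patients.append(p)
    out.patients = patients

    vitals = []
    for v in bundle.vitals:
        changes = {}
        # BMI missingness: drop weight+height together, keeping the BP pair
        if (
            v.weight_kg is not None
            and v.height_cm is not None
            and (v.systolic_mmhg is not None or v.diastolic_mmhg is not None)
            and rng.random() < rates.get("bmi", 0.0)
        ):
            changes["weight_kg"] = None
            changes["height_cm"] = None
            log.missing.append({"table": "vitals", "patient_id": v.patient_id, "field": "bmi"})
        for measure, attr in _VITAL_FIELD_BY_MEASURE.items():
            if changes.get(attr, getattr(v, attr)) is None:
                continue
            if rng.random() < config.implausible_rates.get(measure, 0.0):
                injected = _draw_implausible(rng, measure)
                changes[attr] = injected
                log.implausible.append(
                    {
                        "table": "vitals",
                        "patient_id": v.patient_id,
                        "date": v.measure_date.isoformat(),
                        "measure": measure,
                        "original": getattr(v, attr),
                        "injected": injected,
                    }
                )
        vitals.append(replace(v, **changes) if changes else v)
    out.vitals = vitals

    labs = []
    for l in bundle.labs:
        measure = _LAB_MEASURE_BY_ANALYTE[l.analyte]
        if l.value is not None and rng.random() < config.implausible_rates.get(measure, 0.0):
            injected = _draw_implausible(rng, measure)
            log.implausible.append(
                {
                    "table": "labs",
                    "patient_id": l.patient_id,
                    "date": l.event_date.isoformat(),
                    "measure": measure,
                    "original": l.value,
                    "injected": injected,
                }
            )
            l = replace(l, value=injected)
        labs.append(l)
    out.labs = labs
    return out, log
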