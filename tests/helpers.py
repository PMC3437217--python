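"""Builders for small hand-made bundles and timelines used across tests."""

from __future__ import annotations

from datetime import date

from diabeqc.cohort import PatientTimeline
from diabeqc.model import (
    CareEventRecord,
    DiagnosisRecord,
    EHRBundle,
    Employment,
    InsuranceRole,
    LabRecord,
    MaritalStatus,
    PatientRecord,
    PrescriptionRecord,
    Schooling,
    Sex,
    VisitRecord,
    VisitType,
    VitalRecord,
)

D = date  # shorthand in fixtures


def make_patient(pid: str = "pt-1", clinic: str = "FMC_A", birth: date = D(1960, 6, 15), **kw) -> PatientRecord:
    return PatientRecord(patient_id=pid, clinic_id=clinic, sex=Sex.FEMALE, birth_date=birth, **kw)


def make_bundle(
    patients=(),
    diagnoses=(),
    visits=(),
    vitals=(),
    prescriptions=(),
    labs=(),
    care_events=(),
) -> EHRBundle:
    return EHRBundle(
        patients=list(patients),
        diagnoses=list(diagnoses),
        visits=list(visits),
        vitals=list(vitals),
        prescriptions=list(prescriptions),
        labs=list(labs),
        care_events=list(care_events),
    )


def t2dm_patient_bundle(
    pid: str = "pt-1",
    clinic: str = "FMC_A",
    birth: date = D(1960, 6, 15),
    code: str = "E119",
    code_date: date = D(2008, 3, 1),
    visit_dates=(D(2009, 2, 1),),
    **patient_kw,
) -> EHRBundle:
    """One T2DM-coded patient with family-doctor visits; extend as needed."""
    p = make_patient(pid, clinic, birth, **patient_kw)
    return make_bundle(
        patients=[p],
        diagnoses=[DiagnosisRecord(pid, code, code_date)],
        visits=[VisitRecord(pid, clinic, d, VisitType.FAMILY_DOCTOR) for d in visit_dates],
    )


_TIMELINE_DEFAULTS = dict(
    patient_id="pt-1",
    clinic_id="FMC_A",
    age_years=60,
    sex=Sex.FEMALE,
    schooling=Schooling.PRIMARY,
    marital_status=MaritalStatus.MARRIED_PARTNER,
    employment=Employment.HOUSEWIFE,
    insurance_role=InsuranceRole.DEPENDENT,
    diabetes_duration_years=None,
    contraindications=frozenset(),
    comorbidities=frozenset(),
    complications=frozenset(),
    dyslipidemia_before_window=False,
    bp=[],
    visit_dates=[],
    nutrition_visit_dates=[],
    prescriptions_by_date={},
    care_events=[],
    bmi_first=None,
    bmi_last=None,
)


def make_timeline(**overrides) -> PatientTimeline:
    kw = dict(_TIMELINE_DEFAULTS)
    series = {"hba1c": [], "fasting_glucose": [], "total_cholesterol": [], "weight_kg": [], "height_cm": []}
    series.update(overrides.pop("series", {}))
    kw.update(overrides)
    return PatientTimeline(series=series, **kw)
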