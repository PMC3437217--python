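"""Domain types for flat-file EHR extracts from multi-clinic primary-care systems.

The record types mirror the linked tables of a family-medicine EHR: a patient
registry, ICD-10 coded diagnoses (three diagnosis slots per encounter), visits,
physical measurements, electronic prescriptions, laboratory orders/results and
structured care events (ophthalmology referrals, foot exams). Missing values
are represented as ``None`` for numeric fields and as the ``MISSING`` member of
the corresponding enum for categorical fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from enum import Enum


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    MISSING = "missing"


class Schooling(str, Enum):
    ILLITERATE = "illiterate"
    PRIMARY = "primary"
    SECONDARY = "secondary"
    HIGH_SCHOOL = "high_school"
    UNIVERSITY = "university"
    MISSING = "missing"


class MaritalStatus(str, Enum):
    MARRIED_PARTNER = "married_partner"
    SINGLE_DIVORCED = "single_divorced"
    WIDOWED = "widowed"
    MISSING = "missing"


class Employment(str, Enum):
    HOUSEWIFE = "housewife"
    EMPLOYED = "employed"
    UNEMPLOYED = "unemployed"
    RETIRED = "retired"
    MISSING = "missing"


class InsuranceRole(str, Enum):
    SUBSCRIBER = "subscriber"
    DEPENDENT = "dependent"
    MISSING = "missing"


class Contraindication(str, Enum):
    """Drug classes a patient must not receive ("unless contraindicated")."""

    METFORMIN = "metformin"
    ACEI_ARB = "acei_arb"
    ASA = "asa"
    STATIN = "statin"


class VisitType(str, Enum):
    FAMILY_DOCTOR = "family_doctor"
    NUTRITION_SERVICE = "nutrition_service"
    OTHER = "other"


class Drug(str, Enum):
    METFORMIN = "metformin"
    GLIBENCLAMIDE = "glibenclamide"
    ACARBOSE = "acarbose"
    ROSIGLITAZONE = "rosiglitazone"
    PIOGLITAZONE = "pioglitazone"
    INSULIN = "insulin"
    ACETYLSALICYLIC_ACID = "acetylsalicylic_acid"
    STATIN = "statin"
    ACEI = "acei"
    ARB = "arb"
    OTHER = "other"


#: Oral hypoglycemics plus insulin, used for the prescription-count tables.
HYPOGLYCEMIC_DRUGS = frozenset(
    {
        Drug.METFORMIN,
        Drug.GLIBENCLAMIDE,
        Drug.ACARBOSE,
        Drug.ROSIGLITAZONE,
        Drug.PIOGLITAZONE,
        Drug.INSULIN,
    }
)


class Analyte(str, Enum):
    HBA1C = "hba1c_pct"
    FASTING_GLUCOSE = "fasting_glucose_mg_dl"
    TOTAL_CHOLESTEROL = "total_cholesterol_mg_dl"


class LabStatus(str, Enum):
    ORDERED_ONLY = "ordered_only"
    RESULTED = "resulted"


class CareEventKind(str, Enum):
    OPHTHALMOLOGY_REFERRAL = "ophthalmology_referral"
    FOOT_EXAM = "foot_exam"


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    clinic_id: str
    sex: Sex = Sex.MISSING
    birth_date: date | None = None
    schooling: Schooling = Schooling.MISSING
    marital_status: MaritalStatus = MaritalStatus.MISSING
    employment: Employment = Employment.MISSING
    insurance_role: InsuranceRole = InsuranceRole.MISSING
    diabetes_onset_year: int | None = None
    contraindications: frozenset[Contraindication] = frozenset()


@dataclass(frozen=True)
class DiagnosisRecord:
    patient_id: str
    icd10_code: str
    recorded_date: date
    field_slot: int = 1  # the EHR offers three diagnosis fields per encounter

    def __post_init__(self) -> None:
        if self.field_slot not in (1, 2, 3):
            raise ValueError(f"field_slot must be 1-3, got {self.field_slot}")


@dataclass(frozen=True)
class VisitRecord:
    patient_id: str
    clinic_id: str
    visit_date: date
    visit_type: VisitType = VisitType.FAMILY_DOCTOR


@dataclass(frozen=True)
class VitalRecord:
    patient_id: str
    measure_date: date
    weight_kg: float | None = None
    height_cm: float | None = None
    systolic_mmhg: float | None = None
    diastolic_mmhg: float | None = None

    def __post_init__(self) -> None:
        if (
            self.weight_kg is None
            and self.height_cm is None
            and self.systolic_mmhg is None
            and self.diastolic_mmhg is None
        ):
            raise ValueError("a vitals record needs at least one measurement")


@dataclass(frozen=True)
class PrescriptionRecord:
    patient_id: str
    visit_date: date
    drug: Drug
    daily_dose_mg: float | None = None


@dataclass(frozen=True)
class LabRecord:
    patient_id: str
    event_date: date
    analyte: Analyte
    status: LabStatus
    value: float | None = None

    def __post_init__(self) -> None:
        if (self.status is LabStatus.RESULTED) != (self.value is not None):
            raise ValueError("lab value must be present iff status is resulted")


@dataclass(frozen=True)
class CareEventRecord:
    patient_id: str
    event_date: date
    kind: CareEventKind


@dataclass
class EHRBundle:
    """The full set of linked record tables for one or more clinics."""

    patients: list[PatientRecord] = field(default_factory=list)
    diagnoses: list[DiagnosisRecord] = field(default_factory=list)
    visits: list[VisitRecord] = field(default_factory=list)
    vitals: list[VitalRecord] = field(default_factory=list)
    prescriptions: list[PrescriptionRecord] = field(default_factory=list)
    labs: list[LabRecord] = field(default_factory=list)
    care_events: list[CareEventRecord] = field(default_factory=list)
    #: optional per-clinic registry: clinic_id -> {"members": n, "attendees": n}
    clinic_registry: dict[str, dict[str, int]] | None = None
    #: row-level issues recorded while loading; not part of bundle equality
    load_log: list[dict] = field(default_factory=list, compare=False)

    def patient_ids(self) -> set[str]:
        return {p.patient_id for p in self.patients}

    def validate(self) -> None:
        """Check referential closure and patient-id uniqueness."""
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient_id in bundle")
        known = set(ids)
        for name in ("diagnoses", "visits", "vitals", "prescriptions", "labs", "care_events"):
            for rec in getattr(self, name):
                if rec.patient_id not in known:
                    raise ValueError(f"dangling patient_id {rec.patient_id!r} in {name}")
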