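"""Readers and writers for the flat-file EHR extract.

The extract is a set of comma-delimited UTF-8 tables with header rows, one per
record type (``patients.csv``, ``diagnoses.csv``, ``visits.csv``,
``vitals.csv``, ``prescriptions.csv``, ``labs.csv``, ``care_events.csv`` and an
optional ``clinics.csv`` registry). Missing values are empty cells; the string
"NA" is also accepted on read. Dates are ISO-8601. Drug names are normalised
to the drug-class enum at read time through a configurable synonym map, since
indicators are defined on drug classes rather than products.

Loading is tolerant: rows with unparseable dates or with a ``patient_id``
absent from the patients table are dropped and recorded in the bundle's load
log (one JSON-serialisable entry per dropped row) rather than aborting the
load. A missing required column is a hard :class:`SchemaError`.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping

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


class SchemaError(ValueError):
    """A table is missing a required column."""

    def __init__(self, table: str, column: str) -> None:
        super().__init__(f"table {table!r} is missing required column {column!r}")
        self.table = table
        self.column = column


#: product-name synonyms folded into drug classes on read (all lowercase)
DEFAULT_DRUG_SYNONYMS: dict[str, str] = {
    "aspirin": "acetylsalicylic_acid",
    "asa": "acetylsalicylic_acid",
    "atorvastatin": "statin",
    "simvastatin": "statin",
    "pravastatin": "statin",
    "captopril": "acei",
    "enalapril": "acei",
    "lisinopril": "acei",
    "losartan": "arb",
    "valsartan": "arb",
    "telmisartan": "arb",
}


@dataclass(frozen=True)
class Dialect:
    delimiter: str = ","
    encoding: str = "utf-8"
    date_format: str = "%Y-%m-%d"
    na_values: tuple[str, ...] = ("", "NA")
    drug_synonyms: Mapping[str, str] = field(default_factory=lambda: DEFAULT_DRUG_SYNONYMS)


TABLE_COLUMNS: dict[str, tuple[str, ...]] = {
    "patients": (
        "patient_id",
        "clinic_id",
        "sex",
        "birth_date",
        "schooling",
        "marital_status",
        "employment",
        "insurance_role",
        "diabetes_onset_year",
        "contraindications",
    ),
    "diagnoses": ("patient_id", "icd10_code", "recorded_date", "field_slot"),
    "visits": ("patient_id", "clinic_id", "visit_date", "visit_type"),
    "vitals": (
        "patient_id",
        "measure_date",
        "weight_kg",
        "height_cm",
        "systolic_mmhg",
        "diastolic_mmhg",
    ),
    "prescriptions": ("patient_id", "visit_date", "drug", "daily_dose_mg"),
    "labs": ("patient_id", "event_date", "analyte", "status", "value"),
    "care_events": ("patient_id", "event_date", "kind"),
    "clinics": ("clinic_id", "members", "attendees"),
}

#: canonical file name for each table
TABLE_FILENAMES = {name: f"{name}.csv" for name in TABLE_COLUMNS}


def _is_na(cell: str | None, dialect: Dialect) -> bool:
    return cell is None or cell in dialect.na_values


def _parse_date(cell: str, dialect: Dialect):
    return datetime.strptime(cell, dialect.date_format).date()


def _parse_float(cell: str | None, dialect: Dialect) -> float | None:
    return None if _is_na(cell, dialect) else float(cell)


def _parse_int(cell: str | None, dialect: Dialect) -> int | None:
    return None if _is_na(cell, dialect) else int(cell)


def _parse_enum(enum_cls, cell: str | None, dialect: Dialect):
    if _is_na(cell, dialect):
        return enum_cls("missing")
    return enum_cls(cell)


def _parse_drug(cell: str, dialect: Dialect) -> Drug:
    name = cell.strip().lower()
    name = dialect.drug_synonyms.get(name, name)
    try:
        return Drug(name)
    except ValueError:
        return Drug.OTHER


def _fmt(value) -> str:
    if value is None:
        return ""
    if hasattr(value, "value") and isinstance(value, str):  # str-Enum
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_ehr_bundle(
    table_paths: Mapping[str, str | Path], dialect: Dialect | None = None
) -> EHRBundle:
    """Load a referentially consistent :class:`EHRBundle` from delimited tables.

    ``table_paths`` maps table names (``patients`` ... ``care_events``,
    optionally ``clinics``) to file paths. Rows whose ``patient_id`` does not
    resolve to a patient are dropped and logged; so are rows with unparseable
    dates or malformed values. The load log is attached as ``bundle.load_log``.
    """
    dialect = dialect or Dialect()
    log: list[dict] = []

    def rows(table: str) -> Iterable[tuple[int, dict]]:
        path = Path(table_paths[table])
        with open(path, encoding=dialect.encoding, newline="") as fh:
            reader = csv.DictReader(fh, delimiter=dialect.delimiter)
            header = reader.fieldnames or []
            for col in TABLE_COLUMNS[table]:
                if col not in header:
                    raise SchemaError(table, col)
            for i, row in enumerate(reader, start=2):  # line numbers incl. header
                yield i, row

    bundle = EHRBundle(load_log=log)

    for lineno, row in rows("patients"):
        try:
            contra = frozenset(
                Contraindication(tok)
                for tok in (row["contraindications"] or "").split(";")
                if tok
            )
            birth = (
                None
                if _is_na(row["birth_date"], dialect)
                else _parse_date(row["birth_date"], dialect)
            )
            bundle.patients.append(
                PatientRecord(
                    patient_id=row["patient_id"],
                    clinic_id=row["clinic_id"],
                    sex=_parse_enum(Sex, row["sex"], dialect),
                    birth_date=birth,
                    schooling=_parse_enum(Schooling, row["schooling"], dialect),
                    marital_status=_parse_enum(MaritalStatus, row["marital_status"], dialect),
                    employment=_parse_enum(Employment, row["employment"], dialect),
                    insurance_role=_parse_enum(InsuranceRole, row["insurance_role"], dialect),
                    diabetes_onset_year=_parse_int(row["diabetes_onset_year"], dialect),
                    contraindications=contra,
                )
            )
        except (ValueError, KeyError) as exc:
            log.append(
                {"table": "patients", "row": lineno, "issue": "unparseable_row", "detail": str(exc)}
            )

    known = bundle.patient_ids()

    def checked(table: str, lineno: int, pid: str) -> bool:
        if pid not in known:
            log.append(
                {"table": table, "row": lineno, "patient_id": pid, "issue": "orphan_record"}
            )
            return False
        return True

    for lineno, row in rows("diagnoses"):
        if not checked("diagnoses", lineno, row["patient_id"]):
            continue
        try:
            bundle.diagnoses.append(
                DiagnosisRecord(
                    patient_id=row["patient_id"],
                    icd10_code=row["icd10_code"],
                    recorded_date=_parse_date(row["recorded_date"], dialect),
                    field_slot=int(row["field_slot"]),
                )
            )
        except ValueError as exc:
            log.append(
                {"table": "diagnoses", "row": lineno, "issue": "unparseable_row", "detail": str(exc)}
            )

    for lineno, row in rows("visits"):
        if not checked("visits", lineno, row["patient_id"]):
            continue
        try:
            bundle.visits.append(
                VisitRecord(
                    patient_id=row["patient_id"],
                    clinic_id=row["clinic_id"],
                    visit_date=_parse_date(row["visit_date"], dialect),
                    visit_type=VisitType(row["visit_type"]),
                )
            )
        except ValueError as exc:
            log.append(
                {"table": "visits", "row": lineno, "issue": "unparseable_row", "detail": str(exc)}
            )

    for lineno, row in rows("vitals"):
        if not checked("vitals", lineno, row["patient_id"]):
            continue
        try:
            bundle.vitals.append(
                VitalRecord(
                    patient_id=row["patient_id"],
                    measure_date=_parse_date(row["measure_date"], dialect),
                    weight_kg=_parse_float(row["weight_kg"], dialect),
                    height_cm=_parse_float(row["height_cm"], dialect),
                    systolic_mmhg=_parse_float(row["systolic_mmhg"], dialect),
                    diastolic_mmhg=_parse_float(row["diastolic_mmhg"], dialect),
                )
            )
        except ValueError as exc:
            log.append(
                {"table": "vitals", "row": lineno, "issue": "unparseable_row", "detail": str(exc)}
            )

    for lineno, row in rows("prescriptions"):
        if not checked("prescriptions", lineno, row["patient_id"]):
            continue
        try:
            bundle.prescriptions.append(
                PrescriptionRecord(
                    patient_id=row["patient_id"],
                    visit_date=_parse_date(row["visit_date"], dialect),
                    drug=_parse_drug(row["drug"], dialect),
                    daily_dose_mg=_parse_float(row["daily_dose_mg"], dialect),
                )
            )
        except ValueError as exc:
            log.append(
                {
                    "table": "prescriptions",
                    "row": lineno,
                    "issue": "unparseable_row",
                    "detail": str(exc),
                }
            )

    for lineno, row in rows("labs"):
        if not checked("labs", lineno, row["patient_id"]):
            continue
        try:
            bundle.labs.append(
                LabRecord(
                    patient_id=row["patient_id"],
                    event_date=_parse_date(row["event_date"], dialect),
                    analyte=Analyte(row["analyte"]),
                    status=LabStatus(row["status"]),
                    value=_parse_float(row["value"], dialect),
                )
            )
        except ValueError as exc:
            log.append(
                {"table": "labs", "row": lineno, "issue": "unparseable_row", "detail": str(exc)}
            )

    for lineno, row in rows("care_events"):
        if not checked("care_events", lineno, row["patient_id"]):
            continue
        try:
            bundle.care_events.append(
                CareEventRecord(
                    patient_id=row["patient_id"],
                    event_date=_parse_date(row["event_date"], dialect),
                    kind=CareEventKind(row["kind"]),
                )
            )
        except ValueError as exc:
            log.append(
                {
                    "table": "care_events",
                    "row": lineno,
                    "issue": "unparseable_row",
                    "detail": str(exc),
                }
            )

    if "clinics" in table_paths:
        registry: dict[str, dict[str, int]] = {}
        for lineno, row in rows("clinics"):
            try:
                registry[row["clinic_id"]] = {
                    "members": int(row["members"]),
                    "attendees": int(row["attendees"]),
                }
            except ValueError as exc:
                log.append(
                    {"table": "clinics", "row": lineno, "issue": "unparseable_row", "detail": str(exc)}
                )
        bundle.clinic_registry = registry

    return bundle


def write_analytic_dataset(bundle: EHRBundle, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as one delimited table per record type.

    Returns the table-name -> path mapping, suitable for
    :func:`read_ehr_bundle`. Reading the written files reproduces the bundle
    record for record.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def write(table: str, rows: Iterable[Iterable]) -> None:
        path = directory / TABLE_FILENAMES[table]
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(TABLE_COLUMNS[table])
            for row in rows:
                writer.writerow([_fmt(v) for v in row])
        paths[table] = path

    write(
        "patients",
        (
            (
                p.patient_id,
                p.clinic_id,
                p.sex,
                p.birth_date,
                p.schooling,
                p.marital_status,
                p.employment,
                p.insurance_role,
                p.diabetes_onset_year,
                ";".join(sorted(c.value for c in p.contraindications)),
            )
            for p in bundle.patients
        ),
    )
    write(
        "diagnoses",
        ((d.patient_id, d.icd10_code, d.recorded_date, d.field_slot) for d in bundle.diagnoses),
    )
    write(
        "visits",
        ((v.patient_id, v.clinic_id, v.visit_date, v.visit_type) for v in bundle.visits),
    )
    write(
        "vitals",
        (
            (v.patient_id, v.measure_date, v.weight_kg, v.height_cm, v.systolic_mmhg, v.diastolic_mmhg)
            for v in bundle.vitals
        ),
    )
    write(
        "prescriptions",
        ((p.patient_id, p.visit_date, p.drug, p.daily_dose_mg) for p in bundle.prescriptions),
    )
    write(
        "labs",
        ((l.patient_id, l.event_date, l.analyte, l.status, l.value) for l in bundle.labs),
    )
    write("care_events", ((c.patient_id, c.event_date, c.kind) for c in bundle.care_events))

    if bundle.clinic_registry is not None:
        write(
            "clinics",
            (
                (cid, info["members"], info["attendees"])
                for cid, info in sorted(bundle.clinic_registry.items())
            ),
        )
    return paths


def write_load_log(log: list[dict], path: str | Path) -> None:
    """Write a load/exclusion log as line-oriented JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        for entry in log:
            fh.write(json.dumps(entry, sort_keys=True) + "\n")
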