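"""Independent brute-force re-implementations of cohort selection and
indicator evaluation, written directly from the indicator catalog's prose as
plain scans over raw bundle records. Deliberately shares no code with
diabeqc.cohort / diabeqc.indicators; used only as a test oracle on small
bundles."""

from __future__ import annotations

from datetime import date

from diabeqc.model import (
    Analyte,
    CareEventKind,
    Contraindication,
    Drug,
    EHRBundle,
    LabStatus,
    VisitType,
)

T2DM = (
    {f"E11{i}" for i in range(1, 10)}
    | {f"E14{i}" for i in range(10)}
    | {"E14X", "E14"}
)

LOW = {"sys": 50, "dia": 40, "h": 130, "w": 30, "hba1c": 3.0, "glu": 37, "chol": 100}
HIGH = {"sys": 250, "dia": 200, "h": 250, "w": 200}

INDICATORS = ("p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8", "p9", "o1", "o2", "o3", "o4", "o5")


def _norm(code: str) -> str:
    return code.strip().upper().replace(".", "")


def oracle_cohort(bundle: EHRBundle, year: int = 2009) -> set[str]:
    ws, we = date(year, 1, 1), date(year, 12, 31)
    out = set()
    for p in bundle.patients:
        codes = [
            _norm(d.icd10_code)
            for d in bundle.diagnoses
            if d.patient_id == p.patient_id and d.recorded_date <= we
        ]
        if not any(c in T2DM for c in codes):
            continue
        b = p.birth_date
        age = ws.year - b.year - ((ws.month, ws.day) < (b.month, b.day))
        if age < 20:
            continue
        if not any(
            v.patient_id == p.patient_id
            and v.visit_type == VisitType.FAMILY_DOCTOR
            and ws <= v.visit_date <= we
            for v in bundle.visits
        ):
            continue
        out.add(p.patient_id)
    return out


def oracle_states(bundle: EHRBundle, patient, year: int = 2009) -> dict[str, str]:
    """Tri-state per indicator for one cohort patient: out / den / num."""
    ws, we = date(year, 1, 1), date(year, 12, 31)
    pid = patient.patient_id
    b = patient.birth_date
    age = ws.year - b.year - ((ws.month, ws.day) < (b.month, b.day))
    contra = patient.contraindications

    dx = [d for d in bundle.diagnoses if d.patient_id == pid and d.recorded_date <= we]
    codes = [(_norm(d.icd10_code), d.recorded_date) for d in dx]
    htn = any(c.startswith(tuple(f"I1{i}" for i in range(6))) for c, _ in codes)
    dys = any(c.startswith("E78") for c, _ in codes)
    smoke = any(c.startswith(("F17", "Z720")) for c, _ in codes)
    dys_before = any(c.startswith("E78") and when < ws for c, when in codes)

    visits = sorted(
        {
            v.visit_date
            for v in bundle.visits
            if v.patient_id == pid and v.visit_type == VisitType.FAMILY_DOCTOR and ws <= v.visit_date <= we
        }
    )
    last3 = set(visits[-3:])
    nutrition = any(
        v.patient_id == pid and v.visit_type == VisitType.NUTRITION_SERVICE and ws <= v.visit_date <= we
        for v in bundle.visits
    )

    def drug_last3(drugs, dose=None) -> bool:
        for r in bundle.prescriptions:
            if r.patient_id != pid or r.visit_date not in last3 or r.drug not in drugs:
                continue
            if dose is None:
                return True
            if r.daily_dose_mg is not None and dose[0] <= r.daily_dose_mg <= dose[1]:
                return True
        return False

    def labs(analyte, low):
        return sorted(
            (l.event_date, l.value)
            for l in bundle.labs
            if l.patient_id == pid
            and l.analyte == analyte
            and l.status == LabStatus.RESULTED
            and ws <= l.event_date <= we
            and l.value >= low
        )

    hba1c = labs(Analyte.HBA1C, LOW["hba1c"])
    glucose = labs(Analyte.FASTING_GLUCOSE, LOW["glu"])
    chol = labs(Analyte.TOTAL_CHOLESTEROL, LOW["chol"])

    vit = [v for v in bundle.vitals if v.patient_id == pid and ws <= v.measure_date <= we]
    weights = sorted(
        (v.measure_date, v.weight_kg)
        for v in vit
        if v.weight_kg is not None and LOW["w"] <= v.weight_kg <= HIGH["w"]
    )
    bp = sorted(
        (v.measure_date, v.systolic_mmhg, v.diastolic_mmhg)
        for v in vit
        if v.systolic_mmhg is not None
        and v.diastolic_mmhg is not None
        and LOW["sys"] <= v.systolic_mmhg <= HIGH["sys"]
        and LOW["dia"] <= v.diastolic_mmhg <= HIGH["dia"]
    )
    bmi_pairs = {
        v.measure_date: (v.weight_kg, v.height_cm)
        for v in vit
        if v.weight_kg is not None
        and v.height_cm is not None
        and LOW["w"] <= v.weight_kg <= HIGH["w"]
        and LOW["h"] <= v.height_cm <= HIGH["h"]
    }
    overweight_first = False
    if bmi_pairs:
        w, h = bmi_pairs[min(bmi_pairs)]
        overweight_first = w / (h / 100.0) ** 2 >= 25.0

    foot = any(
        c.patient_id == pid and c.kind == CareEventKind.FOOT_EXAM and ws <= c.event_date <= we
        for c in bundle.care_events
    )
    eye = any(
        c.patient_id == pid
        and c.kind == CareEventKind.OPHTHALMOLOGY_REFERRAL
        and ws <= c.event_date <= we
        for c in bundle.care_events
    )

    glyc_ok = (bool(hba1c) and all(v < 7.0 for _, v in hba1c[-3:])) or (
        bool(glucose) and all(v <= 130.0 for _, v in glucose[-3:])
    )
    chol_ok = bool(chol) and chol[-1][1] < 200.0
    bp_ok = bool(bp) and all(s < 130.0 and d < 80.0 for _, s, d in bp[-3:])
    wl_ok = len(weights) >= 2 and 100.0 * (weights[-1][1] - weights[0][1]) / weights[0][1] <= -5.0

    def tri(elig: bool, numer: bool) -> str:
        if not elig:
            return "out"
        return "num" if numer else "den"

    states = {
        "p1": tri(True, bool(hba1c)),
        "p2": tri(True, foot),
        "p3": tri(True, eye),
        "p4": tri(not dys_before, bool(chol)),
        "p5": tri(True, nutrition),
        "p6": tri(
            overweight_first and Contraindication.METFORMIN not in contra,
            drug_last3({Drug.METFORMIN}),
        ),
        "p7": tri(
            htn and Contraindication.ACEI_ARB not in contra,
            drug_last3({Drug.ACEI, Drug.ARB}),
        ),
        "p8": tri(
            age > 40 and (smoke or htn or dys) and Contraindication.ASA not in contra,
            drug_last3({Drug.ACETYLSALICYLIC_ACID}, (75.0, 150.0)),
        ),
        "p9": tri(
            bool(chol) and chol[-1][1] > 200.0 and Contraindication.STATIN not in contra,
            drug_last3({Drug.STATIN}),
        ),
        "o1": tri(bool(hba1c) or bool(glucose), glyc_ok),
        "o2": tri(bool(chol), chol_ok),
        "o3": tri(bool(bp), bp_ok),
        "o4": tri(
            overweight_first and Contraindication.METFORMIN not in contra and len(weights) >= 2,
            wl_ok,
        ),
    }
    o5_elig = (bool(hba1c) or bool(glucose)) and bool(chol) and bool(bp)
    states["o5"] = tri(o5_elig, glyc_ok and chol_ok and bp_ok)
    return states


def oracle_counts(bundle: EHRBundle, year: int = 2009) -> dict[str, dict[str, tuple[int, int]]]:
    """Per-indicator, per-clinic (numerator, denominator) over the cohort."""
    cohort = oracle_cohort(bundle, year)
    patients = {p.patient_id: p for p in bundle.patients}
    counts: dict[str, dict[str, list[int]]] = {i: {} for i in INDICATORS}
    for pid in cohort:
        p = patients[pid]
        states = oracle_states(bundle, p, year)
        for ind, st in states.items():
            cell = counts[ind].setdefault(p.clinic_id, [0, 0])
            if st != "out":
                cell[1] += 1
            if st == "num":
                cell[0] += 1
    return {
        ind: {cid: (n, d) for cid, (n, d) in cells.items()} for ind, cells in counts.items()
    }
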