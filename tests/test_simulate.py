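"""Synthetic EHR generator: determinism, configured rates, defect injection."""

import math

import pytest

from diabeqc.cohort import ConfigError, plausible, select_cohort
from diabeqc.model import Analyte, LabStatus, Schooling, VisitType
from diabeqc.simulate import (
    SimulationConfig,
    clinic_ids,
    generate_population,
    inject_data_defects,
    simulate_with_truth,
)


def t2dm_code_carriers(bundle):
    from diabeqc.cohort import is_t2dm_code

    return {d.patient_id for d in bundle.diagnoses if is_t2dm_code(d.icd10_code)}


class TestGeneratePopulation:
    def test_zero_members_empty_bundle(self):
        b = generate_population(SimulationConfig(n_clinics=1, members_per_clinic=0, seed=1))
        assert b.patients == [] and b.visits == []

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            generate_population(SimulationConfig(attendance_probability=1.2))

    def test_zero_prevalence_no_t2dm_codes(self):
        cfg = SimulationConfig(
            n_clinics=1,
            members_per_clinic=1200,
            attendance_probability=0.9,
            t2dm_prevalence_among_attendees=0.0,
            seed=2,
        )
        assert t2dm_code_carriers(generate_population(cfg)) == set()

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_clinics=2, members_per_clinic=150, seed=42)
        assert generate_population(cfg) == generate_population(cfg)

    def test_different_seeds_differ(self):
        b1 = generate_population(SimulationConfig(n_clinics=1, members_per_clinic=150, seed=1))
        b2 = generate_population(SimulationConfig(n_clinics=1, members_per_clinic=150, seed=2))
        assert b1 != b2

    def test_prevalence_recovered_within_three_se(self):
        # ~10,000 attendees at 14.4% prevalence
        cfg = SimulationConfig(
            n_clinics=2, members_per_clinic=5600, attendance_probability=0.9, seed=7
        )
        b = generate_population(cfg)
        n = len(b.patients)
        p = cfg.t2dm_prevalence_among_attendees
        se = math.sqrt(p * (1 - p) / n)
        assert abs(len(t2dm_code_carriers(b)) / n - p) <= 3 * se

    def test_visit_mean_recovered(self):
        # 5,000 T2DM patients: sample mean of family-doctor visits near 8.8
        cfg = SimulationConfig(
            n_clinics=1,
            members_per_clinic=5600,
            attendance_probability=0.9,
            t2dm_prevalence_among_attendees=1.0,
            seed=11,
        )
        res = simulate_with_truth(cfg)
        counts = {}
        for v in res.bundle.visits:
            if v.visit_type == VisitType.FAMILY_DOCTOR:
                counts[v.patient_id] = counts.get(v.patient_id, 0) + 1
        per_patient = [counts[pid] for pid in res.truth]
        assert len(per_patient) >= 4500
        mean = sum(per_patient) / len(per_patient)
        assert 8.6 <= mean <= 9.0

    def test_clinic_without_hba1c_capacity_has_no_results(self):
        cfg = SimulationConfig(
            n_clinics=2,
            members_per_clinic=600,
            attendance_probability=0.9,
            hba1c_available_by_clinic=(True, False),
            seed=3,
        )
        b = generate_population(cfg)
        no_lab_clinic = clinic_ids(cfg)[1]
        patients = {p.patient_id: p.clinic_id for p in b.patients}
        for l in b.labs:
            if l.analyte is Analyte.HBA1C and l.status is LabStatus.RESULTED:
                assert patients[l.patient_id] != no_lab_clinic

    def test_full_adherence_gives_universal_referrals(self):
        cfg = SimulationConfig(n_clinics=1, members_per_clinic=300, attendance_probability=0.9, seed=4)
        cfg.indicator_adherence["p3"] = 1.0
        res = simulate_with_truth(cfg)
        referred = {c.patient_id for c in res.bundle.care_events if c.kind.value == "ophthalmology_referral"}
        assert set(res.truth) <= referred

    def test_generated_bundle_is_referentially_closed(self):
        b = generate_population(SimulationConfig(n_clinics=2, members_per_clinic=200, seed=6))
        b.validate()

    def test_all_t2dm_patients_enter_cohort(self):
        # the generator emits cohort-eligible histories: adult, coded, visiting
        res = simulate_with_truth(SimulationConfig(n_clinics=2, members_per_clinic=400, seed=8))
        cohort = select_cohort(res.bundle)
        assert {t.patient_id for t in cohort.timelines} == set(res.truth)


class TestInjectDefects:
    def test_zero_rates_identity(self):
        cfg = SimulationConfig(n_clinics=1, members_per_clinic=200, seed=5)
        cfg.missingness_rates = {k: 0.0 for k in cfg.missingness_rates}
        cfg.implausible_rates = {k: 0.0 for k in cfg.implausible_rates}
        b = generate_population(cfg)
        defected, log = inject_data_defects(b, cfg)
        assert defected == b and log.missing == [] and log.implausible == []

    def test_schooling_rate_one_blanks_every_patient(self):
        cfg = SimulationConfig(n_clinics=1, members_per_clinic=200, seed=5)
        cfg.missingness_rates["schooling"] = 1.0
        b = generate_population(cfg)
        defected, _ = inject_data_defects(b, cfg)
        assert all(p.schooling is Schooling.MISSING for p in defected.patients)

    def test_implausible_weight_rate_recovered(self):
        # ~10,000 vitals rows; injected fraction of weights within 3 SE of 10%
        cfg = SimulationConfig(
            n_clinics=2,
            members_per_clinic=4500,
            attendance_probability=0.9,
            t2dm_prevalence_among_attendees=0.16,
            seed=13,
        )
        cfg.implausible_rates = {"weight_kg": 0.10, "height_cm": 0.0, "systolic": 0.0, "diastolic": 0.0}
        cfg.missingness_rates = {k: 0.0 for k in cfg.missingness_rates}
        b = generate_population(cfg)
        defected, log = inject_data_defects(b, cfg)
        n = sum(1 for v in b.vitals if v.weight_kg is not None)
        assert n >= 10000
        bad = sum(1 for v in defected.vitals if v.weight_kg is not None and not plausible("weight_kg", v.weight_kg))
        se = math.sqrt(0.10 * 0.90 / n)
        assert abs(bad / n - 0.10) <= 3 * se
        assert bad == len(log.implausible)

    def test_record_counts_unchanged(self):
        cfg = SimulationConfig(n_clinics=2, members_per_clinic=300, seed=9)
        b = generate_population(cfg)
        defected, _ = inject_data_defects(b, cfg)
        for table in ("patients", "diagnoses", "visits", "vitals", "prescriptions", "labs", "care_events"):
            assert len(getattr(defected, table)) == len(getattr(b, table))

    def test_vitals_keep_at_least_one_measurement(self):
        cfg = SimulationConfig(n_clinics=1, members_per_clinic=300, seed=10)
        cfg.missingness_rates["bmi"] = 1.0
        defected, _ = inject_data_defects(generate_population(cfg), cfg)
        defected.validate()  # VitalRecord invariant enforced on construction

    def test_injection_deterministic(self):
        cfg = SimulationConfig(n_clinics=1, members_per_clinic=200, seed=12)
        b = generate_population(cfg)
        d1, l1 = inject_data_defects(b, cfg)
        d2, l2 = inject_data_defects(b, cfg)
        assert d1 == d2 and l1.implausible == l2.implausible
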