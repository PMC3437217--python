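"""Cohort selection, plausibility cleaning, BMI, and timeline assembly."""

from datetime import date

import pytest
from hypothesis import given, strategies as st

from diabeqc.cohort import (
    CohortCriteria,
    ConfigError,
    PlausibilityBounds,
    build_timeline,
    classify_bmi,
    clean_measurements,
    compute_bmi,
    dedupe_same_day,
    is_t2dm_code,
    plausible,
    select_cohort,
)
from diabeqc.model import DiagnosisRecord, VisitRecord, VisitType, VitalRecord
from helpers import D, make_bundle, make_patient, t2dm_patient_bundle


class TestDiagnosisCodes:
    @pytest.mark.parametrize(
        "code, expected",
        [
            ("E112", True),
            ("E101", False),  # type 1 family
            ("e14x", True),  # case-insensitive
            ("E11.2", True),  # dotted dialect
            ("E14", True),  # bare stem of the unspecified code
            ("E110", False),  # not in the enumerated set
            ("E149", True),
            ("I10", False),
        ],
    )
    def test_membership(self, code, expected):
        assert is_t2dm_code(code) is expected


class TestPlausibility:
    @pytest.mark.parametrize(
        "measure, value, expected",
        [
            ("systolic", 49, False),
            ("systolic", 50, True),  # the bound itself is retained
            ("systolic", 251, False),
            ("diastolic", 39, False),
            ("fasting_glucose", 36, False),
            ("fasting_glucose", 37, True),
            ("hba1c", 2.9, False),
            ("total_cholesterol", 99, False),
            ("total_cholesterol", 450, True),  # no upper bound by default
            ("weight_kg", 29, False),
            ("weight_kg", 201, False),
            ("height_cm", 130, True),
        ],
    )
    def test_bounds(self, measure, value, expected):
        assert plausible(measure, value) is expected

    def test_unknown_measure_is_config_error(self):
        with pytest.raises(ConfigError):
            plausible("temperature", 37.0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ConfigError):
            PlausibilityBounds(bounds={"weight_kg": (200.0, 30.0)})


class TestCleaning:
    def test_empty(self):
        assert clean_measurements([], "weight_kg") == ([], [])

    def test_removes_out_of_bounds_weights(self):
        series = [(D(2009, 1, 1), 29.0), (D(2009, 2, 1), 80.0), (D(2009, 3, 1), 201.0)]
        kept, log = clean_measurements(series, "weight_kg")
        assert kept == [(D(2009, 2, 1), 80.0)]
        assert len(log) == 2 and all(e["issue"] == "implausible" for e in log)

    def test_sorts_by_date(self):
        series = [(D(2009, 3, 1), 80.0), (D(2009, 1, 1), 70.0)]
        kept, _ = clean_measurements(series, "weight_kg")
        assert kept == [(D(2009, 1, 1), 70.0), (D(2009, 3, 1), 80.0)]

    @given(
        st.lists(
            st.tuples(
                st.dates(min_value=D(2009, 1, 1), max_value=D(2009, 12, 31)),
                st.floats(1, 400, allow_nan=False),
            ),
            max_size=30,
        )
    )
    def test_idempotent(self, series):
        kept, _ = clean_measurements(series, "weight_kg")
        again, log = clean_measurements(kept, "weight_kg")
        assert again == kept and log == []

    def test_same_day_duplicate_keeps_last_loaded(self):
        series = [(D(2009, 1, 5), 70.0), (D(2009, 1, 5), 72.0)]
        kept, log = dedupe_same_day(series)
        assert kept == [(D(2009, 1, 5), 72.0)]
        assert log[0]["issue"] == "same_day_duplicate"


class TestBMI:
    @pytest.mark.parametrize(
        "weight, height, expected",
        [(80, 160, 31.25), (57.6, 160, 22.5), (29, 160, None), (80, None, None)],
    )
    def test_compute(self, weight, height, expected):
        assert compute_bmi(weight, height) == expected

    @pytest.mark.parametrize(
        "bmi, category",
        [
            (18.49, "underweight"),
            (18.5, "normal"),
            (24.9, "normal"),
            (25.0, "overweight"),
            (29.9, "overweight"),
            (30.0, "obese"),
        ],
    )
    def test_classify(self, bmi, category):
        assert classify_bmi(bmi) == category


class TestSelectCohort:
    def test_age_nineteen_excluded_with_reason(self):
        # completed age 19 at the window start: too young despite visits
        b = t2dm_patient_bundle(birth=D(1989, 6, 15), visit_dates=(D(2009, 2, 1), D(2009, 5, 1)))
        cohort = select_cohort(b)
        assert cohort.size() == 0
        assert cohort.exclusion_log == {"pt-1": "age"}

    def test_age_twenty_included(self):
        b = t2dm_patient_bundle(birth=D(1988, 6, 15))
        assert select_cohort(b).size() == 1

    def test_code_in_any_slot_qualifies(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2))
        b.diagnoses = [DiagnosisRecord("pt-1", "E112", D(2008, 3, 1), field_slot=2)]
        assert select_cohort(b).size() == 1

    def test_visits_outside_window_excluded_with_reason(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2), visit_dates=(D(2008, 11, 1),))
        cohort = select_cohort(b)
        assert cohort.size() == 0
        assert cohort.exclusion_log == {"pt-1": "no visit in window"}

    def test_nutrition_visit_does_not_qualify(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2), visit_dates=())
        b.visits = [VisitRecord("pt-1", "FMC_A", D(2009, 3, 1), VisitType.NUTRITION_SERVICE)]
        assert select_cohort(b).exclusion_log == {"pt-1": "no visit in window"}

    def test_non_t2dm_patient_not_logged(self):
        p = make_patient()
        b = make_bundle(patients=[p], diagnoses=[DiagnosisRecord("pt-1", "I10", D(2008, 1, 1))])
        cohort = select_cohort(b)
        assert cohort.size() == 0 and cohort.exclusion_log == {}

    def test_adding_visit_never_removes_from_cohort(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2), visit_dates=(D(2009, 2, 1),))
        included_before = select_cohort(b).size()
        b.visits.append(VisitRecord("pt-1", "FMC_A", D(2009, 9, 9), VisitType.FAMILY_DOCTOR))
        assert select_cohort(b).size() >= included_before


class TestBuildTimeline:
    def test_comorbidity_lookback_unlimited(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2))
        b.diagnoses.append(DiagnosisRecord("pt-1", "I10", D(2007, 5, 1)))
        (t,) = select_cohort(b).timelines
        assert t.has_comorbidity("hypertension")

    def test_dyslipidemia_before_window_flagged_separately(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2))
        b.diagnoses.append(DiagnosisRecord("pt-1", "E780", D(2009, 6, 1)))  # in-window
        (t,) = select_cohort(b).timelines
        assert t.has_comorbidity("dyslipidemia") and not t.dyslipidemia_before_window

    def test_complication_from_fourth_character(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2), code="E112")
        (t,) = select_cohort(b).timelines
        assert "nephropathy" in t.complications

    def test_no_vitals_means_no_bmi(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2))
        (t,) = select_cohort(b).timelines
        assert t.bmi_first is None and t.bmi_last is None

    def test_bmi_first_and_last_from_window_extremes(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2))
        b.vitals = [
            VitalRecord("pt-1", D(2009, 1, 10), weight_kg=80.0, height_cm=160.0),
            VitalRecord("pt-1", D(2009, 11, 10), weight_kg=57.6, height_cm=160.0),
            VitalRecord("pt-1", D(2008, 6, 1), weight_kg=99.0, height_cm=160.0),  # pre-window
        ]
        (t,) = select_cohort(b).timelines
        assert t.bmi_first == (31.25, "obese")
        assert t.bmi_last == (22.5, "normal")

    def test_same_day_weights_keep_last_loaded_and_log(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2))
        b.vitals = [
            VitalRecord("pt-1", D(2009, 1, 10), weight_kg=80.0),
            VitalRecord("pt-1", D(2009, 1, 10), weight_kg=82.0),
        ]
        (t,) = select_cohort(b).timelines
        assert t.series["weight_kg"] == [(D(2009, 1, 10), 82.0)]
        assert any(e["issue"] == "same_day_duplicate" for e in t.cleaning_log)

    def test_bp_pair_dropped_when_either_component_implausible(self):
        b = t2dm_patient_bundle(birth=D(1964, 1, 2))
        b.vitals = [
            VitalRecord("pt-1", D(2009, 1, 10), systolic_mmhg=120.0, diastolic_mmhg=30.0),
            VitalRecord("pt-1", D(2009, 2, 10), systolic_mmhg=120.0, diastolic_mmhg=70.0),
        ]
        (t,) = select_cohort(b).timelines
        assert t.bp == [(D(2009, 2, 10), 120.0, 70.0)]

    def test_diabetes_duration_from_onset_year(self):
        b = t2dm_patient_bundle(birth=D(1950, 1, 2), diabetes_onset_year=2001)
        (t,) = select_cohort(b).timelines
        assert t.diabetes_duration_years == 8
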