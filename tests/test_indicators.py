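"""Indicator engine: measurement-window helpers, rule predicates, evaluation."""

from datetime import date, timedelta

import pytest

from diabeqc.cohort import Cohort, CohortCriteria, PlausibilityBounds
from diabeqc.indicators import (
    NotProgrammableError,
    OutcomeState,
    Tristate,
    bp_control,
    default_catalog,
    evaluate_all,
    evaluate_indicator,
    glycemic_control,
    last_k,
    weight_change_pct,
)
from diabeqc.model import CareEventKind, Contraindication, Drug
from helpers import D, make_timeline

CATALOG = {d.id: d for d in default_catalog()}


def dated(values, start=D(2009, 1, 15)):
    return [(start + timedelta(days=30 * i), float(v)) for i, v in enumerate(values)]


class TestLastK:
    def test_truncates_to_final_three(self):
        assert last_k(["a", "b", "c", "d"], 3) == ["b", "c", "d"]

    def test_short_series_returned_whole(self):
        assert last_k(["a"], 3) == ["a"]

    def test_empty(self):
        assert last_k([], 3) == []


class TestControlStates:
    def test_glucose_controlled_over_last_three(self):
        t = make_timeline(series={"fasting_glucose": dated([140, 128, 130, 125])})
        assert glycemic_control(t) is Tristate.MET  # last three are 128, 130, 125

    def test_hba1c_boundary_is_not_met(self):
        t = make_timeline(series={"hba1c": dated([7.0])})
        assert glycemic_control(t) is Tristate.NOT_MET  # target is strict < 7

    def test_either_analyte_suffices(self):
        t = make_timeline(series={"hba1c": dated([9.0]), "fasting_glucose": dated([110, 120])})
        assert glycemic_control(t) is Tristate.MET

    def test_no_measurements_undetermined(self):
        assert glycemic_control(make_timeline()) is Tristate.UNDETERMINED

    def test_bp_all_three_below_target(self):
        t = make_timeline(bp=[(D(2009, 2, 1), 125, 75), (D(2009, 5, 1), 128, 79), (D(2009, 8, 1), 120, 70)])
        assert bp_control(t) is Tristate.MET

    def test_bp_boundary_not_met(self):
        t = make_timeline(bp=[(D(2009, 2, 1), 130, 79)])
        assert bp_control(t) is Tristate.NOT_MET  # strict < 130

    def test_bp_empty_undetermined(self):
        assert bp_control(make_timeline()) is Tristate.UNDETERMINED

    @pytest.mark.parametrize(
        "first, last, expected", [(100, 94, -6.0), (100, 96, -4.0)]
    )
    def test_weight_change(self, first, last, expected):
        t = make_timeline(series={"weight_kg": dated([first, last])})
        assert weight_change_pct(t) == pytest.approx(expected)

    def test_single_weight_is_missing(self):
        t = make_timeline(series={"weight_kg": dated([100])})
        assert weight_change_pct(t) is None


class TestEvaluateIndicator:
    def _p6_timeline(self, **kw):
        visits = [D(2009, 3, 1), D(2009, 6, 1), D(2009, 9, 1)]
        base = dict(
            visit_dates=visits,
            bmi_first=(27.0, "overweight"),
            prescriptions_by_date={visits[-1]: [(Drug.METFORMIN, 1700.0)]},
        )
        base.update(kw)
        return make_timeline(**base)

    def test_metformin_at_last_visit_is_numerator(self):
        out = evaluate_indicator(CATALOG["p6"], self._p6_timeline())
        assert out.state is OutcomeState.NUMERATOR

    def test_contraindication_excludes_from_denominator(self):
        t = self._p6_timeline(contraindications=frozenset({Contraindication.METFORMIN}))
        assert evaluate_indicator(CATALOG["p6"], t).state is OutcomeState.NOT_IN_DENOMINATOR

    def test_metformin_before_last_three_visits_not_credited(self):
        visits = [D(2009, 1, 5), D(2009, 3, 1), D(2009, 6, 1), D(2009, 9, 1)]
        t = self._p6_timeline(
            visit_dates=visits,
            prescriptions_by_date={visits[0]: [(Drug.METFORMIN, 1700.0)]},
        )
        assert evaluate_indicator(CATALOG["p6"], t).state is OutcomeState.DENOMINATOR_ONLY

    def test_young_patient_not_in_asa_denominator(self):
        t = make_timeline(
            age_years=38,
            comorbidities=frozenset({"smoking"}),
            visit_dates=[D(2009, 3, 1)],
            prescriptions_by_date={D(2009, 3, 1): [(Drug.ACETYLSALICYLIC_ACID, 100.0)]},
        )
        assert evaluate_indicator(CATALOG["p8"], t).state is OutcomeState.NOT_IN_DENOMINATOR

    def test_asa_dose_outside_range_not_credited(self):
        t = make_timeline(
            age_years=55,
            comorbidities=frozenset({"hypertension"}),
            visit_dates=[D(2009, 3, 1)],
            prescriptions_by_date={D(2009, 3, 1): [(Drug.ACETYLSALICYLIC_ACID, 300.0)]},
        )
        assert evaluate_indicator(CATALOG["p8"], t).state is OutcomeState.DENOMINATOR_ONLY

    def test_dyslipidemia_history_excludes_from_screening(self):
        t = make_timeline(
            dyslipidemia_before_window=True,
            series={"total_cholesterol": dated([180])},
        )
        assert evaluate_indicator(CATALOG["p4"], t).state is OutcomeState.NOT_IN_DENOMINATOR

    def test_statin_denominator_needs_high_last_cholesterol(self):
        t = make_timeline(series={"total_cholesterol": dated([220, 195])})
        assert evaluate_indicator(CATALOG["p9"], t).state is OutcomeState.NOT_IN_DENOMINATOR

    def test_inactive_indicator_raises(self):
        with pytest.raises(NotProgrammableError):
            evaluate_indicator(CATALOG["disc_microalbuminuria"], make_timeline())

    def test_tristate_partition(self):
        # every active indicator yields exactly one of the three states
        t = self._p6_timeline()
        for defn in default_catalog():
            if defn.active:
                assert evaluate_indicator(defn, t).state in OutcomeState

    def test_removing_contraindication_never_shrinks_denominator(self):
        flagged = self._p6_timeline(contraindications=frozenset({Contraindication.METFORMIN}))
        clear = self._p6_timeline()
        for ind in ("p6", "o4"):
            before = evaluate_indicator(CATALOG[ind], flagged).state
            after = evaluate_indicator(CATALOG[ind], clear).state
            if before is not OutcomeState.NOT_IN_DENOMINATOR:
                assert after is not OutcomeState.NOT_IN_DENOMINATOR


class TestEvaluateAll:
    def _cohort(self, timelines):
        return Cohort(
            criteria=CohortCriteria(),
            bounds=PlausibilityBounds(),
            timelines=timelines,
            exclusion_log={},
        )

    def test_empty_cohort_gives_empty_denominators(self):
        results = evaluate_all(self._cohort([]))
        assert len(results) == 14
        for r in results:
            assert r.pooled().denominator == 0 and r.pooled().percentage() is None

    def test_single_clinic_pooled_equals_clinic(self):
        visits = [D(2009, 3, 1)]
        t = make_timeline(visit_dates=visits, care_events=[(D(2009, 4, 1), CareEventKind.FOOT_EXAM)])
        results = {r.indicator_id: r for r in evaluate_all(self._cohort([t]))}
        r = results["p2"]
        assert r.pooled().numerator == r.per_clinic["FMC_A"].numerator == 1
        assert r.pooled().denominator == r.per_clinic["FMC_A"].denominator == 1

    def test_counts_match_manual_tally_on_fixture(self):
        # ten patients in two clinics with known foot-exam flags
        timelines = []
        for i in range(10):
            clinic = "FMC_A" if i < 6 else "FMC_B"
            events = [(D(2009, 5, 1), CareEventKind.FOOT_EXAM)] if i % 2 == 0 else []
            timelines.append(
                make_timeline(patient_id=f"pt-{i}", clinic_id=clinic, visit_dates=[D(2009, 3, 1)], care_events=events)
            )
        r = {x.indicator_id: x for x in evaluate_all(self._cohort(timelines))}["p2"]
        assert (r.per_clinic["FMC_A"].numerator, r.per_clinic["FMC_A"].denominator) == (3, 6)
        assert (r.per_clinic["FMC_B"].numerator, r.per_clinic["FMC_B"].denominator) == (2, 4)
        assert r.pooled().numerator == 5

    def test_pooled_percentage_between_clinic_extremes(self):
        timelines = []
        for i in range(20):
            clinic = "FMC_A" if i < 12 else "FMC_B"
            events = [(D(2009, 5, 1), CareEventKind.FOOT_EXAM)] if i % 3 == 0 else []
            timelines.append(
                make_timeline(patient_id=f"pt-{i}", clinic_id=clinic, visit_dates=[D(2009, 3, 1)], care_events=events)
            )
        r = {x.indicator_id: x for x in evaluate_all(self._cohort(timelines))}["p2"]
        pcts = [c.percentage() for c in r.per_clinic.values()]
        assert min(pcts) <= r.pooled().percentage() <= max(pcts)
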