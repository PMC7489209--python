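"""Screening eligibility, the imperfect endoscopy, treatment, surveillance."""

import numpy as np
import pytest

from gcscreen.cohort import Individual
from gcscreen.errors import ModelLogicError
from gcscreen.parameters import TestCharacteristics as EndoscopyTest
from gcscreen.parameters import TreatmentModel, ProcedureOutcomes
from gcscreen.screening import (
    ProcedureEvent,
    ScreeningStrategy,
    TestResult as Result,
    apply_endoscopy,
    builtin_strategies,
    is_screening_due,
    surveillance_step,
    treat_detection,
)
from gcscreen.states import HealthState as S


def _ind(state=S.NORMAL, **kw):
    return Individual(id=0, sex=0, birth_year=1970, health_state=state, **kw)


class TestEligibility:
    def test_start_age_is_due(self):
        assert is_screening_due(50, ScreeningStrategy(50, 75, 3))

    def test_beyond_stop_age(self):
        assert not is_screening_due(76, ScreeningStrategy(50, 75, 2))

    def test_off_cycle_age(self):
        assert not is_screening_due(51, ScreeningStrategy(50, 75, 3))

    def test_due_ages_arithmetic_progression(self):
        ages = ScreeningStrategy(50, 75, 3).due_ages()
        assert ages == list(range(50, 75, 3))
        assert len(ages) == 9  # lifetime maximum screens

    def test_no_stop_age_runs_to_horizon(self):
        s = ScreeningStrategy(50, None, 2)
        assert is_screening_due(100, s)
        assert not is_screening_due(101, s)

    def test_label_round_trip(self):
        for s in (ScreeningStrategy(40, 80, 2), ScreeningStrategy(50, None, 3)):
            assert ScreeningStrategy.from_label(s.label) == s

    def test_builtin_set_has_15_scenarios(self):
        strategies = builtin_strategies()
        assert len(strategies) == 15
        assert strategies.count(None) == 1
        labels = {s.label for s in strategies if s is not None}
        assert {"50-none-2", "50-none-3", "50-75-3", "40-80-2"} <= labels

    def test_biennial_screen_count_dominates_triennial(self):
        # 40-80-2 accumulates at least as many due screens as 50-75-3 by any age
        wide, narrow = ScreeningStrategy(40, 80, 2), ScreeningStrategy(50, 75, 3)
        for age in range(20, 101):
            n_wide = sum(a <= age for a in wide.due_ages())
            n_narrow = sum(a <= age for a in narrow.due_ages())
            assert n_wide >= n_narrow


class TestEndoscopy:
    def test_perfect_sensitivity_finds_lesion(self):
        ind = _ind(S.PRECLINICAL_LOCAL)
        test = EndoscopyTest(sensitivity=1.0, complication_prob=0, death_prob=0)
        result, event = apply_endoscopy(ind, test, np.random.default_rng(0))
        assert result is Result.TRUE_POSITIVE
        assert event is ProcedureEvent.NO_COMPLICATION
        assert ind.endoscopy_count == 1

    def test_perfect_specificity_never_false_positive(self):
        test = EndoscopyTest(specificity=1.0, complication_prob=0, death_prob=0)
        rng = np.random.default_rng(1)
        for _ in range(200):
            result, _ = apply_endoscopy(_ind(S.NORMAL), test, rng)
            assert result is Result.TRUE_NEGATIVE

    def test_false_positive_fraction_matches_specificity(self):
        # base-case specificity 0.851 -> 14.9% false positives in normal mucosa
        test = EndoscopyTest(complication_prob=0, death_prob=0)
        rng = np.random.default_rng(2)
        n = 100_000
        fp = sum(
            apply_endoscopy(_ind(S.NORMAL), test, rng)[0] is Result.FALSE_POSITIVE
            for _ in range(n)
        )
        p = 1 - 0.851
        sd = np.sqrt(n * p * (1 - p))
        assert abs(fp - n * p) < 3 * sd

    def test_procedural_death(self):
        test = EndoscopyTest(death_prob=1.0)
        ind = _ind(S.NORMAL)
        _, event = apply_endoscopy(ind, test, np.random.default_rng(0))
        assert event is ProcedureEvent.PROCEDURAL_DEATH
        assert not ind.alive


class TestTreatment:
    def test_complete_resection_schedules_surveillance(self):
        tm = TreatmentModel(esd=ProcedureOutcomes(1.0, 0.0, 0.0, 0.014))
        ind = _ind(S.DYSPLASIA)
        treat_detection(ind, tm, np.random.default_rng(0))
        assert ind.health_state is S.INTESTINAL_METAPLASIA
        assert ind.surveillance_years_left == 5

    def test_esd_death_is_terminal(self):
        tm = TreatmentModel(esd=ProcedureOutcomes(0.9, 0.0, 1.0, 0.014))
        ind = _ind(S.DYSPLASIA)
        treat_detection(ind, tm, np.random.default_rng(0))
        assert not ind.alive

    def test_incomplete_resection_fraction(self):
        # complete resection 0.90; an inert gastrectomy (resection 0) leaves
        # the incomplete-ESD path in dysplasia, making it countable
        tm = TreatmentModel(
            esd=ProcedureOutcomes(0.90, 0.0, 0.0, 0.014),
            surgery=ProcedureOutcomes(0.0, 0.0, 0.0, 0.004),
        )
        rng = np.random.default_rng(3)
        n = 10_000
        incomplete = 0
        for _ in range(n):
            ind = _ind(S.DYSPLASIA)
            treat_detection(ind, tm, rng)
            incomplete += ind.health_state is S.DYSPLASIA
        sd = np.sqrt(n * 0.9 * 0.1)
        assert abs(incomplete - 0.1 * n) < 3 * sd

    def test_screen_detected_cancer_diagnosed_same_stage(self):
        tm = TreatmentModel(surgery=ProcedureOutcomes(1.0, 0.0, 0.0, 0.004))
        ind = _ind(S.PRECLINICAL_REGIONAL)
        ind.age = 60
        treat_detection(ind, tm, np.random.default_rng(0))
        assert ind.health_state is S.CLINICAL_REGIONAL
        assert ind.diagnosis == (1, 60)

    def test_negative_result_rejected(self):
        with pytest.raises(ModelLogicError):
            treat_detection(_ind(S.DYSPLASIA), TreatmentModel(), np.random.default_rng(0), Result.TRUE_NEGATIVE)


class TestSurveillance:
    def test_five_years_without_recurrence(self):
        test = EndoscopyTest(complication_prob=0, death_prob=0)
        tm = TreatmentModel(esd=ProcedureOutcomes(0.9, 0.0, 0.0, 0.0))  # recurrence 0
        ind = _ind(S.INTESTINAL_METAPLASIA, surveillance_years_left=5)
        rng = np.random.default_rng(0)
        for _ in range(5):
            surveillance_step(ind, test, tm, rng)
        assert ind.surveillance_years_left == 0
        assert ind.endoscopy_count == 5
        assert ind.health_state is S.INTESTINAL_METAPLASIA

    def test_recurrence_probability_closed_form(self):
        # P(>=1 recurrence in 5 years) = 1 - 0.986^5 = 0.0681; with test
        # sensitivity zero a recurrence is never re-treated, so ending in
        # dysplasia marks exactly the ever-recurred individuals.
        test = EndoscopyTest(sensitivity=0.0, complication_prob=0, death_prob=0)
        tm = TreatmentModel()  # esd recurrence 0.014
        rng = np.random.default_rng(8)
        n = 20_000
        recurred = 0
        for _ in range(n):
            ind = _ind(S.INTESTINAL_METAPLASIA, surveillance_years_left=5)
            for _ in range(5):
                surveillance_step(ind, test, tm, rng)
            recurred += ind.health_state is S.DYSPLASIA
        expected = 1 - 0.986**5
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(recurred / n - expected) < 3 * se

    def test_no_step_without_years_left(self):
        with pytest.raises(ModelLogicError):
            surveillance_step(_ind(S.INTESTINAL_METAPLASIA), EndoscopyTest(), TreatmentModel(), np.random.default_rng(0))
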