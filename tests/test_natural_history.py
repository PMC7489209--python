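"""Correa-cascade transitions, survival draws, and incidence summaries."""

import numpy as np
import pandas as pd
import pytest

from gcscreen.cohort import CURRENT, Individual
from gcscreen.errors import ModelLogicError
from gcscreen.natural_history import (
    SurvivalModel,
    advance_state,
    incidence_table,
    sample_gc_survival,
    transition_probability,
)
from gcscreen.parameters import TransitionParameters
from gcscreen.states import HealthState as S


def _ind(state=S.NORMAL, hp=False, smoking=0):
    return Individual(id=0, sex=0, birth_year=1970, health_state=state, hp_infected=hp, smoking=smoking)


class TestTransitionProbability:
    def test_hp_multiplier_product(self):
        p = TransitionParameters(p_normal_ag=0.02, rr_hp=3.0)
        got = transition_probability(S.NORMAL, S.ATROPHIC_GASTRITIS, _ind(hp=True), p)
        assert got == pytest.approx(0.06)

    def test_identity_with_unit_multipliers(self):
        p = TransitionParameters(rr_hp=1.0, rr_smoker_current=1.0, rr_smoker_former=1.0)
        for a, b, base in [
            (S.NORMAL, S.ATROPHIC_GASTRITIS, p.p_normal_ag),
            (S.ATROPHIC_GASTRITIS, S.INTESTINAL_METAPLASIA, p.p_ag_im),
            (S.DYSPLASIA, S.PRECLINICAL_LOCAL, p.p_dys_local),
        ]:
            assert transition_probability(a, b, _ind(state=a, hp=True, smoking=CURRENT), p) == base

    def test_clipped_at_one(self):
        p = TransitionParameters(p_normal_ag=0.6, rr_hp=2.0)
        assert transition_probability(S.NORMAL, S.ATROPHIC_GASTRITIS, _ind(hp=True), p) == 1.0

    def test_disallowed_edge_rejected(self):
        with pytest.raises(ModelLogicError):
            transition_probability(S.NORMAL, S.DYSPLASIA, _ind(), TransitionParameters())

    def test_smoking_only_on_initiation_edges(self):
        p = TransitionParameters(p_dys_local=0.05, rr_smoker_current=2.0)
        got = transition_probability(S.DYSPLASIA, S.PRECLINICAL_LOCAL, _ind(state=S.DYSPLASIA, smoking=CURRENT), p)
        assert got == pytest.approx(0.05)


class TestAdvanceState:
    def test_all_zero_parameters_freeze_state(self):
        zero = {k: 0.0 for k in TransitionParameters.PROB_FIELDS}
        p = TransitionParameters(**zero)
        rng = np.random.default_rng(0)
        for state in (S.NORMAL, S.DYSPLASIA, S.PRECLINICAL_DISTANT):
            ind = _ind(state=state)
            advance_state(ind, p, rng)
            assert ind.health_state == state

    def test_certain_progression_dysplasia(self):
        p = TransitionParameters(p_dys_local=1.0)
        ind = _ind(state=S.DYSPLASIA)
        advance_state(ind, p, np.random.default_rng(0))
        assert ind.health_state == S.PRECLINICAL_LOCAL

    def test_symptom_detection_sets_diagnosis(self):
        p = TransitionParameters(s_regional=1.0)
        ind = _ind(state=S.PRECLINICAL_REGIONAL)
        advance_state(ind, p, np.random.default_rng(0))
        assert ind.health_state == S.CLINICAL_REGIONAL
        assert ind.diagnosis == (1, 20)

    def test_progression_fraction_binomial(self):
        n, p0 = 100_000, 0.03
        params = TransitionParameters(p_normal_ag=p0, rr_hp=1.0)
        rng = np.random.default_rng(2)
        count = 0
        for i in range(n):
            ind = _ind()
            advance_state(ind, params, rng)
            count += ind.health_state == S.ATROPHIC_GASTRITIS
        sd = np.sqrt(n * p0 * (1 - p0))
        assert abs(count - n * p0) < 3 * sd


class TestSurvival:
    def test_certain_first_year_death(self):
        hz = np.zeros((2, 3, 3))
        hz[:, :, 0] = 1.0
        assert sample_gc_survival(0, 1, SurvivalModel(hz), np.random.default_rng(0)) == 1

    def test_zero_hazard_never_dies(self):
        surv = SurvivalModel(np.zeros((2, 3, 3)))
        assert sample_gc_survival(0, 0, surv, np.random.default_rng(0)) is None

    def test_constant_hazard_five_year_survival(self):
        # S(5) = (1 - 0.3)^5 = 0.16807 under a constant annual hazard
        surv = SurvivalModel(np.full((2, 3, 1), 0.3))
        rng = np.random.default_rng(9)
        n = 100_000
        alive5 = 0
        for _ in range(n):
            t = sample_gc_survival(0, 2, surv, rng, max_years=5)
            alive5 += t is None
        expected = 0.7**5
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(alive5 / n - expected) < 3 * se

    def test_hazard_constant_beyond_followup(self):
        hz = np.zeros((2, 3, 2))
        hz[:, :, 1] = 0.25
        m = SurvivalModel(hz)
        assert float(m.annual_probability(0, 0, 10)) == 0.25


class TestIncidenceTable:
    def test_hand_tally(self):
        # 10 people contribute person-years in two ages; 3 diagnoses at 52
        dx = pd.DataFrame({"age": [52, 52, 52], "sex": [0, 0, 1], "stage": [0, 1, 0]})
        py = pd.DataFrame(
            {"age": [52, 52, 57], "sex": [0, 1, 0], "person_years": [1000.0, 500.0, 200.0]}
        )
        rates, stages = incidence_table(dx, py, age_groups=np.array([50, 55]))
        r = rates.set_index(["age_group", "sex"])["rate_per_100k"]
        assert r[(50, 0)] == pytest.approx(1e5 * 2 / 1000)
        assert r[(50, 1)] == pytest.approx(1e5 * 1 / 500)
        assert r[(55, 0)] == pytest.approx(0.0)

    def test_stage_rows_sum_to_one(self):
        dx = pd.DataFrame({"age": [60] * 6, "sex": [0, 0, 0, 1, 1, 1], "stage": [0, 1, 2, 0, 0, 2]})
        py = pd.DataFrame({"age": [60], "sex": [0], "person_years": [100.0]})
        _, stages = incidence_table(dx, py)
        sums = stages.groupby("sex")["proportion"].sum()
        assert np.allclose(sums, 1.0)

    def test_empty_stratum_is_missing_not_zero(self):
        dx = pd.DataFrame({"age": [], "sex": [], "stage": []})
        py = pd.DataFrame({"age": [30], "sex": [0], "person_years": [100.0]})
        rates, stages = incidence_table(dx, py, age_groups=np.array([25, 30]))
        r = rates.set_index(["age_group", "sex"])["rate_per_100k"]
        assert np.isnan(r[(25, 0)])  # no person-years -> missing
        assert r[(30, 0)] == 0.0  # person-years but no cases -> true zero
        assert stages["proportion"].isna().all()
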