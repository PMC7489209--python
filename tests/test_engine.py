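"""Whole-engine behaviour: determinism, degenerate worlds, invariants."""

import numpy as np
import pandas as pd
import pytest

from gcscreen.engine import RunConfig, Simulator
from gcscreen.errors import ConfigurationError
from gcscreen.parameters import ModelInputs, TransitionParameters, UtilitySchedule
from gcscreen.screening import ScreeningStrategy

from conftest import const_schedules, zero_survival

ZERO_PARAMS = TransitionParameters(**{k: 0.0 for k in TransitionParameters.PROB_FIELDS})


def _zero_world(q=0.0, **inputs_kw):
    return Simulator(const_schedules(q=q), zero_survival(), ZERO_PARAMS, ModelInputs(**inputs_kw))


class TestDeterminism:
    def test_same_seed_identical_outcomes(self, simulator):
        a = simulator.simulate_strategy(ScreeningStrategy(50, 75, 3), n=5000, seed=13)
        b = simulator.simulate_strategy(ScreeningStrategy(50, 75, 3), n=5000, seed=13)
        assert (a.gc_deaths, a.endoscopies, a.qalys_disc, a.cost_disc) == (
            b.gc_deaths,
            b.endoscopies,
            b.qalys_disc,
            b.cost_disc,
        )

    def test_run_all_reproducible(self, simulator):
        cfg = RunConfig(n_individuals=3000, seed=4, strategies=[None, ScreeningStrategy(50, 75, 3)])
        pd.testing.assert_frame_equal(simulator.run_all(cfg), simulator.run_all(cfg))


class TestDegenerateWorlds:
    def test_immortal_cohort_reaches_horizon(self):
        sim = _zero_world()
        out = sim.simulate_strategy(None, n=2000, seed=0)
        pop = out.final_population
        assert pop.alive.all()
        assert out.gc_deaths == 0
        # 80 full years of perfect health each
        assert out.qalys_undisc == pytest.approx(80.0 * 2000)

    def test_screens_equal_due_ages_in_disease_free_world(self):
        # with no disease and inert test hazards, endoscopies per person are
        # exactly the due ages reached before death
        sim = _zero_world(q=0.02)
        sim.inputs.test.complication_prob = 0.0
        sim.inputs.test.death_prob = 0.0
        strat = ScreeningStrategy(50, 75, 3)
        out = sim.simulate_strategy(strat, n=5000, seed=1)
        pop = out.final_population
        due = np.array(strat.due_ages())
        death_age = np.where(pop.age_at_death < 0, 101, pop.age_at_death)
        expected = (due[None, :] < death_age[:, None]).sum(axis=1)
        np.testing.assert_array_equal(pop.endoscopies, expected)

    def test_no_screening_after_stop_age(self, simulator):
        out = simulator.simulate_strategy(ScreeningStrategy(50, 75, 2), n=2000, seed=2)
        # max possible: 13 screens (50..74) + 5 surveillance per treatment; a
        # loose structural cap that fails if eligibility leaks past the stop age
        assert out.final_population.endoscopies.max() <= 13 + 15


class TestEpidemiologicalInvariants:
    def test_equal_rates_without_risk_multipliers(self, fixtures):
        schedules, survival, truth = fixtures
        neutral = truth.replace(rr_hp=1.0, rr_smoker_current=1.0, rr_smoker_former=1.0)
        sim = Simulator(schedules, survival, neutral)
        out = sim.simulate_strategy(None, n=100_000, seed=21)
        pop = out.final_population
        inf, uninf = pop.hp_infected, ~pop.hp_infected
        p1 = pop.diagnosed[inf].mean()
        p2 = pop.diagnosed[uninf].mean()
        pbar = pop.diagnosed.mean()
        z = (p1 - p2) / np.sqrt(pbar * (1 - pbar) * (1 / inf.sum() + 1 / uninf.sum()))
        assert abs(z) < 2.576  # alpha = 0.01

    def test_infected_progress_faster_with_multipliers(self, simulator):
        out = simulator.simulate_strategy(None, n=100_000, seed=22)
        pop = out.final_population
        assert pop.diagnosed[pop.hp_infected].mean() > 2 * pop.diagnosed[~pop.hp_infected].mean()

    def test_monte_carlo_convergence_of_death_rate(self, simulator):
        small = simulator.simulate_strategy(None, n=50_000, seed=30)
        large = simulator.simulate_strategy(None, n=150_000, seed=31)
        p1, p2 = small.gc_deaths / small.n, large.gc_deaths / large.n
        se = np.sqrt(p1 * (1 - p1) / small.n + p2 * (1 - p2) / large.n)
        assert abs(p1 - p2) < 3 * se


class TestLedgers:
    def test_qaly_ordering(self, simulator):
        out = simulator.simulate_strategy(None, n=20_000, seed=5)
        pop = out.final_population
        lived = np.where(pop.age_at_death < 0, 80, pop.age_at_death - 20)
        assert np.all(pop.qaly_disc <= pop.qaly_undisc + 1e-9)
        assert np.all(pop.qaly_undisc <= lived + 1e-9)

    def test_unit_utilities_give_discounted_life_years(self, fixtures):
        schedules, survival, truth = fixtures
        inputs = ModelInputs(utilities=UtilitySchedule(local=1.0, regional=1.0, distant=1.0))
        sim = Simulator(schedules, survival, truth, inputs)
        out = sim.simulate_strategy(None, n=20_000, seed=6)
        pop = out.final_population
        dfe = 1.03 ** -np.arange(80)
        cum = np.concatenate([[0.0], np.cumsum(dfe)])
        lived = np.where(pop.age_at_death < 0, 80, pop.age_at_death - 20)
        np.testing.assert_allclose(pop.qaly_disc, cum[lived], rtol=1e-12)

    def test_costs_nonnegative_and_monotone_with_screening(self, simulator):
        cfg = RunConfig(
            n_individuals=20_000, seed=8, strategies=[None, ScreeningStrategy(50, 75, 3)]
        )
        df = simulator.run_all(cfg).set_index("strategy")
        assert (df["cost_per_1000_thousands"] >= 0).all()
        assert df.loc["50-75-3", "cost_per_1000_thousands"] > df.loc["none", "cost_per_1000_thousands"]


class TestRunAll:
    def test_missing_anchor_rejected(self, simulator):
        cfg = RunConfig(n_individuals=100, seed=0, strategies=[ScreeningStrategy(50, 75, 3), ScreeningStrategy(50, 80, 3)])
        with pytest.raises(ConfigurationError):
            simulator.run_all(cfg)

    def test_builtin_scenario_table_schema(self, simulator):
        from gcscreen.screening import builtin_strategies

        cfg = RunConfig(n_individuals=500, seed=1, strategies=builtin_strategies())
        df = simulator.run_all(cfg)
        assert len(df) == 15
        assert list(df.columns) == [
            "strategy",
            "gc_deaths_per_1000",
            "gc_mortality_reduction_pct",
            "endoscopies_per_1000",
            "qalys_gained_per_1000",
            "cost_per_1000_thousands",
        ]
        assert (df.loc[df["strategy"] == "none", "qalys_gained_per_1000"] == 0).all()
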