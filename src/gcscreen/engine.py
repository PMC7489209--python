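"""Yearly simulation loop over individuals and strategies.

The engine advances the whole cohort one model year at a time with
vectorised numpy operations; an individual's year is: (1) smoking update,
(2) other-cause death, (3) screening if due (including post-ESD
surveillance), (4) natural-history transition and gastric-cancer death,
(5) cost/QALY accrual.

Common random numbers: the natural-history stream draws a fixed block of
uniforms per (individual, year) regardless of state or strategy, so disease
trajectories are identical across screening arms except where screening
itself intervened; screening consumes a separate stream.  This removes
almost all Monte-Carlo noise from incremental comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import AGE_ENTRY, AGE_MAX, CURRENT, FORMER, NEVER, Population, RiskSchedules, create_population
from .errors import ConfigurationError
from .natural_history import SurvivalModel, incidence_table
from .parameters import ModelInputs, TransitionParameters
from .screening import ScreeningStrategy, is_screening_due
from .states import CAUSE_GC, CAUSE_OTHER, HealthState

S = HealthState
_NORMAL, _AG, _IM, _DYS = int(S.NORMAL), int(S.ATROPHIC_GASTRITIS), int(S.INTESTINAL_METAPLASIA), int(S.DYSPLASIA)
_PRE_L, _PRE_R, _PRE_D = int(S.PRECLINICAL_LOCAL), int(S.PRECLINICAL_REGIONAL), int(S.PRECLINICAL_DISTANT)
_CL_L = int(S.CLINICAL_LOCAL)


@dataclass
class StrategyOutcome:
    """Lifetime outcomes of one strategy for a simulated cohort."""

    label: str
    n: int
    gc_deaths: int
    other_deaths: int
    cancers_diagnosed: int
    endoscopies: int
    qalys_disc: float
    qalys_undisc: float
    cost_disc: float
    qalys_gained_per_1000: float | None = None  # vs the no-screening arm

    def _per_1000(self, x: float) -> float:
        return 1000.0 * x / self.n

    @property
    def gc_deaths_per_1000(self) -> float:
        return self._per_1000(self.gc_deaths)

    @property
    def endoscopies_per_1000(self) -> float:
        return self._per_1000(self.endoscopies)

    @property
    def qalys_disc_per_1000(self) -> float:
        return self._per_1000(self.qalys_disc)

    @property
    def cost_disc_per_1000_thousands(self) -> float:
        """Discounted total cost per 1000 individuals, in $1000s (table units)."""
        return self._per_1000(self.cost_disc) / 1000.0


@dataclass
class SimulationRecord:
    """Optional per-run epidemiological bookkeeping for calibration."""

    diagnoses: pd.DataFrame
    person_years: pd.DataFrame


@dataclass
class RunConfig:
    """Configuration of a multi-strategy run."""

    n_individuals: int
    seed: int
    strategies: list[ScreeningStrategy | None] = field(default_factory=list)
    birth_year_range: tuple[int, int] = (1965, 1985)
    sex_ratio: float = 0.5


class Simulator:
    """Binds fixtures (schedules, survival, natural history, economics)
    and runs strategies over a common virtual population."""

    def __init__(
        self,
        schedules: RiskSchedules,
        survival: SurvivalModel,
        params: TransitionParameters,
        inputs: ModelInputs | None = None,
    ):
        self.schedules = schedules
        self.survival = survival
        self.params = params
        self.inputs = inputs if inputs is not None else ModelInputs()

    # ------------------------------------------------------------------
    def make_population(self, n: int, seed, birth_year_range=(1965, 1985), sex_ratio=0.5) -> Population:
        return create_population(n, self.schedules, seed, birth_year_range, sex_ratio)

    def simulate_strategy(
        self,
        strategy: ScreeningStrategy | None,
        n: int | None = None,
        seed: int | None = None,
        population: Population | None = None,
        seed_seq: np.random.SeedSequence | None = None,
        collect_incidence: bool = False,
    ) -> StrategyOutcome | tuple[StrategyOutcome, SimulationRecord]:
        """Run one strategy to the model horizon and aggregate ledgers.

        Either pass ``n`` and ``seed`` (a fresh population is drawn) or a
        pre-built ``population`` plus the ``seed_seq`` whose spawned streams
        drive events; the latter form is what ``run_all`` uses to share the
        population and random streams across strategies.
        """
        if population is None:
            if n is None or seed is None:
                raise ConfigurationError("need n and seed when no population is given")
            seed_seq = np.random.SeedSequence(seed)
            pop_ss, nh_ss, sc_ss = seed_seq.spawn(3)
            population = self.make_population(n, pop_ss)
        else:
            if seed_seq is None:
                raise ConfigurationError("need seed_seq when a population is given")
            _pop_ss, nh_ss, sc_ss = seed_seq.spawn(3)
        pop = population.copy()
        record = self._run(pop, strategy, nh_ss, sc_ss, collect_incidence)
        label = "none" if strategy is None else strategy.label
        out = StrategyOutcome(
            label=label,
            n=pop.n,
            gc_deaths=int((pop.cause == CAUSE_GC).sum()),
            other_deaths=int((pop.cause == CAUSE_OTHER).sum()),
            cancers_diagnosed=int(pop.diagnosed.sum()),
            endoscopies=int(pop.endoscopies.sum()),
            qalys_disc=float(pop.qaly_disc.sum()),
            qalys_undisc=float(pop.qaly_undisc.sum()),
            cost_disc=float(pop.cost_disc.sum()),
        )
        out.final_population = pop  # inspectable by tests
        if collect_incidence:
            return out, record
        return out

    # ------------------------------------------------------------------
    def _run(self, pop: Population, strategy, nh_ss, sc_ss, collect_incidence: bool):
        p = self.params
        inp = self.inputs
        costs, util = inp.costs, inp.utilities
        esd, surg = inp.treatment.esd, inp.treatment.surgery
        sens, spec = inp.test.sensitivity, inp.test.specificity
        n = pop.n
        nh_rng = np.random.default_rng(nh_ss)
        sc_rng = np.random.default_rng(sc_ss)

        kmax = AGE_MAX - AGE_ENTRY
        dfc = (1.0 + inp.discount.rate_costs) ** -np.arange(kmax)
        dfe = (1.0 + inp.discount.rate_effects) ** -np.arange(kmax)
        stage_util = np.asarray(util.stage_utilities())
        wage = costs.hourly_wage
        endo_cost = costs.endoscopy + costs.hours_endoscopy * wage
        compl_cost = costs.complication_expected
        esd_cost = costs.esd + costs.hours_esd * wage
        surg_cost = costs.hours_surgery * wage  # direct surgical cost is in stage costs
        first_cost = np.asarray(costs.first_year) + costs.hours_first_year * wage
        subs_cost = np.asarray(costs.subsequent_year) + costs.hours_subsequent_year * wage
        term_cost = costs.terminal_year + costs.hours_final_year * wage
        d_endo = util.decrement_years("endoscopy")
        d_endo_c = util.decrement_years("endoscopy_complication")
        d_surg = util.decrement_years("surgery")
        d_surg_c = util.decrement_years("surgery_complication")

        base_prog = np.zeros(10)
        base_prog[[_NORMAL, _AG, _IM, _DYS, _PRE_L, _PRE_R]] = [
            p.p_normal_ag, p.p_ag_im, p.p_im_dys, p.p_dys_local, p.p_local_regional, p.p_regional_distant,
        ]
        sym_p = np.zeros(10)
        sym_p[[_PRE_L, _PRE_R, _PRE_D]] = [p.s_local, p.s_regional, p.s_distant]

        if collect_incidence:
            py_count = np.zeros((kmax, 2))
            dx_count_rows: list[tuple[int, int, int]] = []

        for k in range(kmax):
            age = AGE_ENTRY + k
            u_smoke, u_od, u_sym, u_prog, u_gc = nh_rng.random((5, n))
            year = pop.birth_year + age
            alive = pop.alive
            event_cost = np.zeros(n)
            decr = np.zeros(n)

            if collect_incidence:
                at_risk = alive & ~pop.diagnosed
                py_count[k] += np.bincount(pop.sex[at_risk], minlength=2)

            # --- 0. annual risk-factor (smoking) update -------------------
            init_p = self.schedules.smoking_initiation.lookup(age, pop.sex, year)
            cess_p = self.schedules.smoking_cessation.lookup(age, pop.sex, year)
            starts = alive & (pop.smoking == NEVER) & (u_smoke < init_p)
            quits = alive & (pop.smoking == CURRENT) & (u_smoke < cess_p)
            pop.smoking[starts] = CURRENT
            pop.smoking[quits] = FORMER

            # --- 1. competing (other-cause) mortality ---------------------
            q = self.schedules.lifetable.lookup(age, pop.sex, year)
            dies = alive & (u_od < q)
            pop.alive[dies] = False
            pop.cause[dies] = CAUSE_OTHER
            pop.age_at_death[dies] = age
            alive = pop.alive

            new_dx = np.zeros(n, dtype=bool)
            died_gc_now = np.zeros(n, dtype=bool)

            # --- 2. screening --------------------------------------------
            if strategy is not None:
                in_surv = alive & (pop.surveillance_left > 0) & ~pop.diagnosed
                due = alive & ~pop.diagnosed & ~in_surv
                if is_screening_due(age, strategy):
                    if inp.adherence < 1.0:
                        due &= sc_rng.random(n) < inp.adherence
                else:
                    due &= False
                screened = in_surv | due
                sidx = np.flatnonzero(screened)
                if sidx.size:
                    # recurrence of resected dysplasia surfaces before the
                    # surveillance endoscopy, so it can be found this year
                    surv_idx = np.flatnonzero(in_surv)
                    if surv_idx.size:
                        u_rec = sc_rng.random(surv_idx.size)
                        rec = surv_idx[(pop.state[surv_idx] == _IM) & (u_rec < pop.recurrence_prob[surv_idx])]
                        pop.state[rec] = _DYS
                        pop.surveillance_left[surv_idx] -= 1
                        done = surv_idx[pop.surveillance_left[surv_idx] == 0]
                        pop.recurrence_prob[done] = 0.0

                    ns = sidx.size
                    pop.endoscopies[sidx] += 1
                    u_res, u_compl, u_pdeath = sc_rng.random((3, ns))
                    lesion = (pop.state[sidx] >= _DYS) & (pop.state[sidx] <= _PRE_D)
                    positive = np.where(lesion, u_res < sens, u_res < 1.0 - spec)
                    compl = u_compl < inp.test.complication_prob
                    event_cost[sidx] += endo_cost + np.where(compl, compl_cost, 0.0)
                    decr[sidx] += np.where(compl, d_endo_c, d_endo)
                    pdeath = u_pdeath < inp.test.death_prob
                    pd_idx = sidx[pdeath]
                    pop.alive[pd_idx] = False
                    pop.cause[pd_idx] = CAUSE_OTHER
                    pop.age_at_death[pd_idx] = age

                    tp_idx = sidx[positive & lesion & ~pdeath]
                    # dysplasia -> ESD (incomplete resection -> gastrectomy)
                    dys_idx = tp_idx[pop.state[tp_idx] == _DYS]
                    if dys_idx.size:
                        m = dys_idx.size
                        u_edeath, u_ecompl, u_eres = sc_rng.random((3, m))
                        ecompl = u_ecompl < esd.complication
                        event_cost[dys_idx] += esd_cost + np.where(ecompl, compl_cost, 0.0)
                        decr[dys_idx] += np.where(ecompl, d_surg_c, d_surg)
                        edead = u_edeath < esd.death
                        dd = dys_idx[edead]
                        pop.alive[dd] = False
                        pop.cause[dd] = CAUSE_OTHER
                        pop.age_at_death[dd] = age
                        alive_d = dys_idx[~edead]
                        complete = u_eres[~edead] < esd.complete_resection
                        ok = alive_d[complete]
                        pop.state[ok] = _IM
                        pop.surveillance_left[ok] = 5
                        pop.recurrence_prob[ok] = esd.annual_recurrence
                        inc = alive_d[~complete]
                        if inc.size:
                            mm = inc.size
                            u_sdeath, u_scompl, u_sres = sc_rng.random((3, mm))
                            scompl = u_scompl < surg.complication
                            event_cost[inc] += surg_cost + np.where(scompl, compl_cost, 0.0)
                            decr[inc] += np.where(scompl, d_surg_c, d_surg)
                            sdead = u_sdeath < surg.death
                            sd = inc[sdead]
                            pop.alive[sd] = False
                            pop.cause[sd] = CAUSE_OTHER
                            pop.age_at_death[sd] = age
                            salive = inc[~sdead]
                            resected = u_sres[~sdead] < surg.complete_resection
                            pop.state[salive[resected]] = _IM
                            pop.surveillance_left[salive] = 5
                            pop.recurrence_prob[salive] = surg.annual_recurrence
                    # screen-detected preclinical cancer -> clinical diagnosis
                    ca_idx = tp_idx[(pop.state[tp_idx] >= _PRE_L) & (pop.state[tp_idx] <= _PRE_D)]
                    if ca_idx.size:
                        stage = (pop.state[ca_idx] - _PRE_L).astype(np.int8)
                        self._diagnose(pop, ca_idx, stage, age)
                        new_dx[ca_idx] = True
                        loc = ca_idx[stage == 0] if inp.local_cancer_surgery else np.empty(0, dtype=int)
                        if loc.size:
                            mm = loc.size
                            u_sdeath, u_scompl = sc_rng.random((2, mm))
                            scompl = u_scompl < surg.complication
                            event_cost[loc] += surg_cost + np.where(scompl, compl_cost, 0.0)
                            decr[loc] += np.where(scompl, d_surg_c, d_surg)
                            sdead = u_sdeath < surg.death
                            sd = loc[sdead]
                            pop.alive[sd] = False
                            pop.cause[sd] = CAUSE_OTHER
                            pop.age_at_death[sd] = age
                alive = pop.alive

            # --- 3. natural history --------------------------------------
            und = alive & ~pop.diagnosed
            st = pop.state
            sym = und & (u_sym < sym_p[st])
            mult = np.ones(n)
            hp_edge = (st == _NORMAL) | (st == _AG)
            mult[hp_edge & pop.hp_infected] *= p.rr_hp
            sm_edge = hp_edge | (st == _IM)
            mult[sm_edge & (pop.smoking == CURRENT)] *= p.rr_smoker_current
            mult[sm_edge & (pop.smoking == FORMER)] *= p.rr_smoker_former
            pp = np.minimum(1.0, base_prog[st] * mult)
            prog = und & ~sym & (u_prog < pp)

            sym_idx = np.flatnonzero(sym)
            if sym_idx.size:
                stage = (st[sym_idx] - _PRE_L).astype(np.int8)
                self._diagnose(pop, sym_idx, stage, age)
                new_dx[sym_idx] = True
            pop.state[prog] += 1

            if collect_incidence:
                ndx = np.flatnonzero(new_dx)
                for i in ndx:
                    dx_count_rows.append((age, int(pop.sex[i]), int(pop.diag_stage[i])))

            # gastric-cancer death among the diagnosed
            dgc_idx = np.flatnonzero(pop.alive & pop.diagnosed)
            if dgc_idx.size:
                hz = self.survival.annual_probability(
                    pop.sex[dgc_idx], pop.diag_stage[dgc_idx], pop.years_since_diagnosis[dgc_idx]
                )
                die = u_gc[dgc_idx] < hz
                gcd = dgc_idx[die]
                pop.alive[gcd] = False
                pop.cause[gcd] = CAUSE_GC
                pop.age_at_death[gcd] = age
                died_gc_now[gcd] = True

            # --- 4. annual accrual ---------------------------------------
            alive_end = pop.alive
            u_state = np.where(pop.diagnosed, stage_util[np.clip(pop.diag_stage, 0, 2)], util.healthy)
            qal = np.where(alive_end, np.maximum(0.0, u_state * (1.0 - decr)), 0.0)
            pop.qaly_disc += qal * dfe[k]
            pop.qaly_undisc += qal

            stage_cost = np.zeros(n)
            active = pop.diagnosed & (alive_end | died_gc_now)
            sidx_c = np.clip(pop.diag_stage, 0, 2)
            first = active & new_dx & ~died_gc_now
            subs = active & ~new_dx & ~died_gc_now
            stage_cost[first] = first_cost[sidx_c[first]]
            stage_cost[subs] = subs_cost[sidx_c[subs]]
            stage_cost[active & died_gc_now] = term_cost
            pop.cost_disc += (event_cost + stage_cost) * dfc[k]

            pop.years_since_diagnosis[pop.diagnosed & alive_end] += 1

        if collect_incidence:
            dx_df = pd.DataFrame(dx_count_rows, columns=["age", "sex", "stage"])
            py_rows = []
            for k in range(kmax):
                for sex in (0, 1):
                    py_rows.append((AGE_ENTRY + k, sex, py_count[k, sex]))
            py_df = pd.DataFrame(py_rows, columns=["age", "sex", "person_years"])
            return SimulationRecord(dx_df, py_df)
        return None

    @staticmethod
    def _diagnose(pop: Population, idx, stage, age: int) -> None:
        pop.diagnosed[idx] = True
        pop.diag_stage[idx] = stage
        pop.age_at_diagnosis[idx] = age
        pop.years_since_diagnosis[idx] = 0
        pop.state[idx] = _CL_L + stage

    # ------------------------------------------------------------------
    def run_all(self, config: RunConfig) -> pd.DataFrame:
        """Simulate every strategy over one shared population.

        Returns a table with one row per strategy: gastric-cancer deaths and
        endoscopies per 1000 (undiscounted), discounted QALYs gained vs the
        no-screening anchor, and discounted total cost in $1000s per 1000.
        """
        if not any(s is None for s in config.strategies):
            raise ConfigurationError("strategy set must include the no-screening anchor")
        if len(config.strategies) < 2:
            raise ConfigurationError("need at least two strategies")
        root = np.random.SeedSequence(config.seed)
        pop_ss = root.spawn(1)[0]
        population = self.make_population(
            config.n_individuals, pop_ss, config.birth_year_range, config.sex_ratio
        )
        outcomes: list[StrategyOutcome] = []
        for strat in config.strategies:
            # identical seed_seq per strategy -> common random numbers
            out = self.simulate_strategy(
                strat, population=population, seed_seq=np.random.SeedSequence(config.seed)
            )
            outcomes.append(out)
        anchor = next(o for o in outcomes if o.label == "none")
        for o in outcomes:
            o.qalys_gained_per_1000 = o.qalys_disc_per_1000 - anchor.qalys_disc_per_1000
        rows = [
            {
                "strategy": o.label,
                "gc_deaths_per_1000": o.gc_deaths_per_1000,
                "gc_mortality_reduction_pct": 100.0 * (1.0 - o.gc_deaths / anchor.gc_deaths)
                if anchor.gc_deaths
                else np.nan,
                "endoscopies_per_1000": o.endoscopies_per_1000,
                "qalys_gained_per_1000": o.qalys_gained_per_1000,
                "cost_per_1000_thousands": o.cost_disc_per_1000_thousands,
            }
            for o in outcomes
        ]
        df = pd.DataFrame(rows)
        df.attrs["outcomes"] = outcomes
        return df

    # ------------------------------------------------------------------
    def incidence_summary(self, n: int, seed: int, age_groups=None):
        """No-screening run summarised as incidence rates and stage distribution."""
        _out, rec = self.simulate_strategy(None, n=n, seed=seed, collect_incidence=True)
        return incidence_table(rec.diagnoses, rec.person_years, age_groups)
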