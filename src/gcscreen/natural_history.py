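"""Disease-state machine: Correa-cascade progression, symptomatic
detection, and post-diagnosis survival.

Progression is forward-only: normal mucosa -> atrophic gastritis ->
intestinal metaplasia -> dysplasia -> preclinical local -> regional ->
distant cancer.  Each preclinical stage competes every year between becoming
symptomatic (clinical diagnosis at the same stage) and progressing to the
next stage; symptom detection is evaluated first.  Risk multipliers for
*H. pylori* infection and smoking act on the precancer-initiation edges:
``rr_hp`` on normal->AG and AG->IM, the smoking multipliers additionally on
IM->dysplasia.

Post-diagnosis survival follows stage-, sex- and year-since-diagnosis-
specific annual gastric-cancer death probabilities; beyond the tabulated
follow-up the last hazard applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CURRENT, FORMER, Individual
from .errors import ConfigurationError, ModelLogicError
from .parameters import TransitionParameters
from .states import (
    DISTANT,
    FORWARD_EDGES,
    LOCAL,
    REGIONAL,
    SEX_NAMES,
    STAGE_NAMES,
    HealthState,
    stage_of,
)

S = HealthState

# forward progression target for each progressing state
_NEXT_STATE = {
    S.NORMAL: S.ATROPHIC_GASTRITIS,
    S.ATROPHIC_GASTRITIS: S.INTESTINAL_METAPLASIA,
    S.INTESTINAL_METAPLASIA: S.DYSPLASIA,
    S.DYSPLASIA: S.PRECLINICAL_LOCAL,
    S.PRECLINICAL_LOCAL: S.PRECLINICAL_REGIONAL,
    S.PRECLINICAL_REGIONAL: S.PRECLINICAL_DISTANT,
}

_BASE_PARAM = {
    S.NORMAL: "p_normal_ag",
    S.ATROPHIC_GASTRITIS: "p_ag_im",
    S.INTESTINAL_METAPLASIA: "p_im_dys",
    S.DYSPLASIA: "p_dys_local",
    S.PRECLINICAL_LOCAL: "p_local_regional",
    S.PRECLINICAL_REGIONAL: "p_regional_distant",
}

_SYMPTOM_PARAM = {
    S.PRECLINICAL_LOCAL: "s_local",
    S.PRECLINICAL_REGIONAL: "s_regional",
    S.PRECLINICAL_DISTANT: "s_distant",
}

# edges on which the H. pylori multiplier acts, and those for smoking
HP_EDGES = {S.NORMAL, S.ATROPHIC_GASTRITIS}
SMOKING_EDGES = {S.NORMAL, S.ATROPHIC_GASTRITIS, S.INTESTINAL_METAPLASIA}


def risk_multiplier(state: HealthState, hp_infected: bool, smoking: int, params: TransitionParameters) -> float:
    """Combined relative-risk multiplier for the progression edge out of ``state``."""
    m = 1.0
    if state in HP_EDGES and hp_infected:
        m *= params.rr_hp
    if state in SMOKING_EDGES:
        if smoking == CURRENT:
            m *= params.rr_smoker_current
        elif smoking == FORMER:
            m *= params.rr_smoker_former
    return m


def transition_probability(
    state: HealthState,
    target: HealthState,
    ind: Individual,
    params: TransitionParameters,
) -> float:
    """Annual probability of the (state -> target) edge for one individual.

    Raises :class:`ModelLogicError` for edges not on the forward chain.
    """
    if (state, target) not in FORWARD_EDGES:
        raise ModelLogicError(f"transition {state.name} -> {target.name} is not an allowed edge")
    if target in (S.CLINICAL_LOCAL, S.CLINICAL_REGIONAL, S.CLINICAL_DISTANT):
        base = getattr(params, _SYMPTOM_PARAM[state])
        return float(min(1.0, base))
    base = getattr(params, _BASE_PARAM[state])
    p = base * risk_multiplier(state, ind.hp_infected, ind.smoking, params)
    return float(min(1.0, p))


def advance_state(ind: Individual, params: TransitionParameters, rng: np.random.Generator) -> Individual:
    """One annual natural-history step for an undiagnosed individual.

    At most one forward transition per year.  Preclinical states first draw
    symptomatic detection (moving to the same-stage clinical state and
    recording the diagnosis), then, if still asymptomatic, progression to
    the next stage.
    """
    if not ind.alive:
        raise ModelLogicError(f"individual {ind.id} is not alive")
    state = ind.health_state
    u_sym, u_prog = rng.random(2)
    if state in _SYMPTOM_PARAM:
        if u_sym < getattr(params, _SYMPTOM_PARAM[state]):
            stage = stage_of(state)
            ind.health_state = (S.CLINICAL_LOCAL, S.CLINICAL_REGIONAL, S.CLINICAL_DISTANT)[stage]
            ind.diagnosis = (stage, ind.age)
            return ind
    if state in _BASE_PARAM:
        p = getattr(params, _BASE_PARAM[state])
        p = min(1.0, p * risk_multiplier(state, ind.hp_infected, ind.smoking, params))
        if u_prog < p:
            ind.health_state = _NEXT_STATE[state]
    return ind


@dataclass
class SurvivalModel:
    """Annual gastric-cancer death probability by (sex, stage, year since diagnosis).

    ``hazard`` has shape (2 sexes, 3 stages, n_years); the final column
    applies to all later years (long-term survivors remain subject to
    other-cause mortality only through the life table).
    """

    hazard: np.ndarray

    def __post_init__(self) -> None:
        self.hazard = np.asarray(self.hazard, dtype=float)
        if self.hazard.ndim != 3 or self.hazard.shape[:2] != (2, 3):
            raise ConfigurationError("survival hazard must have shape (2, 3, n_years)")
        if np.any(self.hazard < 0) or np.any(self.hazard > 1):
            raise ConfigurationError("survival hazards must lie in [0, 1]")

    @property
    def n_years(self) -> int:
        return self.hazard.shape[2]

    def annual_probability(self, sex, stage, years_since_diagnosis):
        """Vectorised lookup; ``years_since_diagnosis`` is 0-based (0 = first year)."""
        yi = np.minimum(np.asarray(years_since_diagnosis), self.n_years - 1)
        return self.hazard[np.asarray(sex), np.asarray(stage), yi]

    def to_csv(self, path) -> None:
        rows = []
        for si, sex in enumerate(SEX_NAMES):
            for ti, stage in enumerate(STAGE_NAMES):
                for y in range(self.n_years):
                    rows.append((sex, stage, y + 1, self.hazard[si, ti, y]))
        pd.DataFrame(rows, columns=["sex", "stage", "year", "hazard"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SurvivalModel":
        df = pd.read_csv(path)
        n_years = df["year"].max()
        hz = np.zeros((2, 3, n_years))
        sex_idx = {name: i for i, name in enumerate(SEX_NAMES)}
        stage_idx = {name: i for i, name in enumerate(STAGE_NAMES)}
        for _, r in df.iterrows():
            hz[sex_idx[r["sex"]], stage_idx[r["stage"]], int(r["year"]) - 1] = r["hazard"]
        return cls(hz)


def sample_gc_survival(
    sex: int,
    stage: int,
    survival: SurvivalModel,
    rng: np.random.Generator,
    max_years: int = 80,
) -> int | None:
    """Draw years from diagnosis to gastric-cancer death.

    Returns the 1-based year of death (death during year k of follow-up), or
    ``None`` if the individual survives ``max_years`` annual hazard draws
    (censoring horizon; in the engine the horizon is age 100).
    """
    for k in range(max_years):
        if rng.random() < float(survival.annual_probability(sex, stage, k)):
            return k + 1
    return None


def incidence_table(
    diagnoses: pd.DataFrame,
    person_years: pd.DataFrame,
    age_groups: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Age- and sex-specific incidence rates and stage distribution.

    Parameters
    ----------
    diagnoses
        One row per incident clinical diagnosis with columns
        ``age``, ``sex``, ``stage``.
    person_years
        Columns ``age``, ``sex``, ``person_years``: years at risk (alive and
        undiagnosed) accumulated at each age.
    age_groups
        Left edges of the age bins (default: 5-year bins from 20 to 100).

    Returns
    -------
    (rates, stage_dist)
        ``rates``: columns ``age_group``, ``sex``, ``rate_per_100k`` (NaN for
        empty strata rather than zero).  ``stage_dist``: per sex, proportions
        over local/regional/distant summing to 1.
    """
    if age_groups is None:
        age_groups = np.arange(20, 100, 5)
    age_groups = np.asarray(age_groups)

    def _bin(ages):
        return age_groups[np.clip(np.searchsorted(age_groups, ages, side="right") - 1, 0, len(age_groups) - 1)]

    py = person_years.copy()
    py["age_group"] = _bin(py["age"].to_numpy())
    py_g = py.groupby(["age_group", "sex"])["person_years"].sum()

    dx = diagnoses.copy()
    rows = []
    if len(dx):
        dx["age_group"] = _bin(dx["age"].to_numpy())
        counts = dx.groupby(["age_group", "sex"]).size()
    else:
        counts = pd.Series(dtype=int)
    for ag in age_groups:
        for sex in (0, 1):
            denom = py_g.get((ag, sex), 0.0)
            num = counts.get((ag, sex), 0)
            rate = np.nan if denom == 0 else 1e5 * num / denom
            rows.append((ag, sex, rate))
    rates = pd.DataFrame(rows, columns=["age_group", "sex", "rate_per_100k"])

    stage_rows = []
    for sex in (0, 1):
        sub = dx[dx["sex"] == sex] if len(dx) else dx
        total = len(sub)
        for stage in (LOCAL, REGIONAL, DISTANT):
            prop = np.nan if total == 0 else (sub["stage"] == stage).sum() / total
            stage_rows.append((sex, stage, prop))
    stage_dist = pd.DataFrame(stage_rows, columns=["sex", "stage", "proportion"])
    return rates, stage_dist
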