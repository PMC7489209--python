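"""Endoscopic screening strategies, the imperfect endoscopy test,
ESD / surgical treatment of screen-detected lesions, and post-ESD
surveillance.

A strategy is a (start age, stop age, interval) triple written
``start-stop-interval`` (for example ``50-75-3``); a stop age of ``none``
means screening continues to the model horizon (age 100).  Screen-positive
dysplasia is treated by endoscopic submucosal dissection (ESD) with yearly
surveillance endoscopy for 5 years; incomplete resection is referred to
gastrectomy.  Screen-detected preclinical cancer is diagnosed at its current
(earlier) stage, which is the mechanism of the survival benefit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import yaml

from .cohort import Individual
from .errors import ConfigurationError, ModelLogicError
from .parameters import TestCharacteristics, TreatmentModel
from .states import CAUSE_OTHER, LESION_STATES, HealthState, stage_of

S = HealthState


@dataclass(frozen=True)
class ScreeningStrategy:
    """Eligibility rule: screen at start, start+interval, ... up to stop."""

    start_age: int
    stop_age: int | None
    interval: int

    @property
    def label(self) -> str:
        stop = "none" if self.stop_age is None else str(self.stop_age)
        return f"{self.start_age}-{stop}-{self.interval}"

    @classmethod
    def from_label(cls, label: str) -> "ScreeningStrategy":
        try:
            start, stop, interval = label.split("-")
            return cls(int(start), None if stop == "none" else int(stop), int(interval))
        except (ValueError, TypeError) as exc:
            raise ConfigurationError(f"bad strategy label {label!r}") from exc

    def due_ages(self, horizon: int = 100) -> list[int]:
        stop = horizon if self.stop_age is None else self.stop_age
        return list(range(self.start_age, min(stop, horizon) + 1, self.interval))


def is_screening_due(age: int, strategy: ScreeningStrategy | None, horizon: int = 100) -> bool:
    """True if a screen falls at this (integer) age under the strategy."""
    if strategy is None:
        return False
    stop = horizon if strategy.stop_age is None else strategy.stop_age
    return strategy.start_age <= age <= min(stop, horizon) and (age - strategy.start_age) % strategy.interval == 0


#: The 15 evaluated scenarios: no screening, the two current-guideline
#: strategies (start 50, no stopping age), and 12 start/stop/interval
#: combinations.
def builtin_strategies() -> list[ScreeningStrategy | None]:
    strategies: list[ScreeningStrategy | None] = [None]
    for interval in (3, 2):
        strategies.append(ScreeningStrategy(50, None, interval))
    for interval in (2, 3):
        for start in (50, 45, 40):
            for stop in (75, 80):
                strategies.append(ScreeningStrategy(start, stop, interval))
    return strategies


def load_strategies(path) -> list[ScreeningStrategy | None]:
    """Read a strategy set from YAML: a list of {start, stop, interval} maps."""
    with open(path) as fh:
        items = yaml.safe_load(fh)
    out: list[ScreeningStrategy | None] = []
    for item in items:
        if item is None or item == "none":
            out.append(None)
        else:
            out.append(ScreeningStrategy(int(item["start"]), item.get("stop"), int(item["interval"])))
    return out


class TestResult(enum.Enum):
    TRUE_POSITIVE = "true_positive"
    FALSE_NEGATIVE = "false_negative"
    FALSE_POSITIVE = "false_positive"
    TRUE_NEGATIVE = "true_negative"


class ProcedureEvent(enum.Enum):
    NO_COMPLICATION = "no_complication"
    COMPLICATION = "complication"
    PROCEDURAL_DEATH = "procedural_death"


def apply_endoscopy(
    ind: Individual,
    test: TestCharacteristics,
    rng: np.random.Generator,
) -> tuple[TestResult, ProcedureEvent]:
    """One screening endoscopy with biopsy on a living individual.

    Lesion states (dysplasia, preclinical cancer) test positive with
    probability ``sensitivity``; all other states test positive with
    probability ``1 - specificity``.  Complications and procedural death are
    drawn independently of the test result.
    """
    if not ind.alive:
        raise ModelLogicError(f"individual {ind.id} is not alive")
    ind.endoscopy_count += 1
    u_result, u_compl, u_death = rng.random(3)
    lesion = ind.health_state in LESION_STATES
    positive = u_result < (test.sensitivity if lesion else 1.0 - test.specificity)
    if lesion:
        result = TestResult.TRUE_POSITIVE if positive else TestResult.FALSE_NEGATIVE
    else:
        result = TestResult.FALSE_POSITIVE if positive else TestResult.TRUE_NEGATIVE
    if u_death < test.death_prob:
        ind.alive = False
        ind.cause_of_death = CAUSE_OTHER
        return result, ProcedureEvent.PROCEDURAL_DEATH
    event = ProcedureEvent.COMPLICATION if u_compl < test.complication_prob else ProcedureEvent.NO_COMPLICATION
    return result, event


def treat_detection(
    ind: Individual,
    treatment: TreatmentModel,
    rng: np.random.Generator,
    result: TestResult = TestResult.TRUE_POSITIVE,
) -> Individual:
    """Treat a true-positive screening finding.

    Dysplasia: ESD; complete resection removes the lesion (back to
    intestinal metaplasia) and schedules 5 years of surveillance with the
    ESD recurrence risk; incomplete resection is referred to gastrectomy.
    Preclinical cancer: clinical diagnosis at the same stage; local disease
    is treated surgically.
    """
    if result is not TestResult.TRUE_POSITIVE:
        raise ModelLogicError("treat_detection requires a true-positive result")
    state = ind.health_state
    if state is S.DYSPLASIA:
        u_death, u_resect = rng.random(2)
        if u_death < treatment.esd.death:
            ind.alive = False
            ind.cause_of_death = CAUSE_OTHER
            return ind
        if u_resect < treatment.esd.complete_resection:
            ind.health_state = S.INTESTINAL_METAPLASIA
            ind.surveillance_years_left = 5
            return ind
        # incomplete resection -> gastrectomy
        u_sdeath, u_sresect = rng.random(2)
        if u_sdeath < treatment.surgery.death:
            ind.alive = False
            ind.cause_of_death = CAUSE_OTHER
            return ind
        if u_sresect < treatment.surgery.complete_resection:
            ind.health_state = S.INTESTINAL_METAPLASIA
        ind.surveillance_years_left = 5
        return ind
    if state in (S.PRECLINICAL_LOCAL, S.PRECLINICAL_REGIONAL, S.PRECLINICAL_DISTANT):
        stage = stage_of(state)
        ind.health_state = (S.CLINICAL_LOCAL, S.CLINICAL_REGIONAL, S.CLINICAL_DISTANT)[stage]
        ind.diagnosis = (stage, ind.age)
        if stage == 0:
            u_sdeath = rng.random()
            if u_sdeath < treatment.surgery.death:
                ind.alive = False
                ind.cause_of_death = CAUSE_OTHER
        return ind
    raise ModelLogicError(f"treat_detection on non-lesion state {state.name}")


def surveillance_step(
    ind: Individual,
    test: TestCharacteristics,
    treatment: TreatmentModel,
    rng: np.random.Generator,
    recurrence_prob: float | None = None,
) -> Individual:
    """One yearly post-ESD surveillance endoscopy.

    The recurrence draw (lesion returning as dysplasia) precedes the
    endoscopy, so a recurrence arising this year can be found this year with
    the test's sensitivity and re-treated.
    """
    if ind.surveillance_years_left <= 0:
        raise ModelLogicError("surveillance_step with no surveillance years left")
    p_rec = treatment.esd.annual_recurrence if recurrence_prob is None else recurrence_prob
    if ind.health_state is S.INTESTINAL_METAPLASIA and rng.random() < p_rec:
        ind.health_state = S.DYSPLASIA
    result, _event = apply_endoscopy(ind, test, rng)
    ind.surveillance_years_left -= 1
    if ind.alive and result is TestResult.TRUE_POSITIVE and ind.health_state is S.DYSPLASIA:
        treat_detection(ind, treatment, rng)
    return ind
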