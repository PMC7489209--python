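import numpy as np
import pytest

from gcscreen.cohort import BirthYearCurve, RiskSchedules, Schedule3D
from gcscreen.engine import Simulator
from gcscreen.natural_history import SurvivalModel
from gcscreen.synthetic_data import SyntheticConfig, make_fixtures

AGES = 81  # ages 20..100


def const_schedules(hp=0.3, init=0.0, cess=0.0, q=0.0) -> RiskSchedules:
    """Constant-probability schedules covering all reachable (age, sex, year)."""

    def s3(v, name):
        return Schedule3D(np.full((AGES, 2, 1), v), 20, 1985, name=name)

    return RiskSchedules(
        hp_prevalence=BirthYearCurve(np.full(96, hp), 1908),
        smoking_initiation=s3(init, "smoking_initiation"),
        smoking_cessation=s3(cess, "smoking_cessation"),
        lifetable=s3(q, "lifetable"),
    )


def zero_survival(n_years=5) -> SurvivalModel:
    return SurvivalModel(np.zeros((2, 3, n_years)))


@pytest.fixture(scope="session")
def fixtures():
    """Default synthetic input bundle (schedules, survival, ground truth)."""
    return make_fixtures(SyntheticConfig())


@pytest.fixture(scope="session")
def simulator(fixtures):
    schedules, survival, truth = fixtures
    return Simulator(schedules, survival, truth)
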