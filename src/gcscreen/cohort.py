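"""Virtual population: demographics, birth-cohort *H. pylori* status,
annually updated smoking behaviour, and competing (other-cause) mortality.

Individuals enter the model at age 20 and are followed until death or age
100.  *H. pylori* infection is assigned once at entry from a birth-cohort
prevalence curve (reflecting the secular decline in infection across
Japanese birth cohorts); smoking status is updated every simulated year from
age/sex/calendar-year initiation and cessation schedules; other-cause death
competes with gastric cancer through a period life table.

The population is stored as a struct-of-arrays (:class:`Population`) so the
engine can advance everyone one year at a time with vectorised numpy
operations.  :class:`Individual` is a scalar view used by the per-person
operations and in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ModelLogicError
from .states import CAUSE_NONE, CAUSE_OTHER, FEMALE, MALE, HealthState

AGE_ENTRY = 20
AGE_MAX = 100

NEVER, CURRENT, FORMER = 0, 1, 2
SMOKING_NAMES = ("never", "current", "former")


class Schedule3D:
    """Dense (age, sex, calendar year) probability lookup table.

    Years outside the covered range are clamped to the nearest covered year
    (schedules are slowly varying); ages outside the covered range raise a
    :class:`ConfigurationError` naming the missing key.
    """

    def __init__(self, values: np.ndarray, age0: int, year0: int, name: str = "schedule"):
        values = np.asarray(values, dtype=float)
        if values.ndim != 3 or values.shape[1] != 2:
            raise ConfigurationError(f"{name}: expected shape (n_ages, 2, n_years)")
        if np.any(values < 0) or np.any(values > 1):
            raise ConfigurationError(f"{name}: probabilities must lie in [0, 1]")
        self.values = values
        self.age0 = int(age0)
        self.year0 = int(year0)
        self.name = name

    @property
    def age1(self) -> int:
        return self.age0 + self.values.shape[0] - 1

    def lookup(self, age, sex, year):
        """Vectorised lookup; ``age`` may be a scalar, ``sex``/``year`` arrays."""
        age = np.asarray(age)
        if np.any(age < self.age0) or np.any(age > self.age1):
            bad = int(np.atleast_1d(age)[(np.atleast_1d(age) < self.age0) | (np.atleast_1d(age) > self.age1)][0])
            raise ConfigurationError(f"{self.name}: no entry for age={bad} (covers {self.age0}-{self.age1})")
        yi = np.clip(np.asarray(year) - self.year0, 0, self.values.shape[2] - 1)
        return self.values[age - self.age0, np.asarray(sex), yi]

    def to_frame(self) -> pd.DataFrame:
        ages = np.arange(self.age0, self.age1 + 1)
        years = self.year0 + np.arange(self.values.shape[2])
        idx = pd.MultiIndex.from_product([ages, (MALE, FEMALE), years], names=["age", "sex", "year"])
        return pd.DataFrame({"value": self.values.ravel()}, index=idx).reset_index()

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "schedule") -> "Schedule3D":
        required = {"age", "sex", "year", "value"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"{name}: CSV must have columns {sorted(required)}")
        ages = np.sort(df["age"].unique())
        years = np.sort(df["year"].unique())
        piv = df.set_index(["age", "sex", "year"])["value"]
        try:
            values = piv.sort_index().to_numpy().reshape(len(ages), 2, len(years))
        except ValueError as exc:
            raise ConfigurationError(f"{name}: incomplete (age, sex, year) grid") from exc
        return cls(values, int(ages[0]), int(years[0]), name=name)


class BirthYearCurve:
    """Probability indexed by birth year (used for *H. pylori* prevalence)."""

    def __init__(self, values: np.ndarray, birth_year0: int, name: str = "hp_prevalence"):
        values = np.asarray(values, dtype=float)
        if np.any(values < 0) or np.any(values > 1):
            raise ConfigurationError(f"{name}: probabilities must lie in [0, 1]")
        if np.any(np.diff(values) > 1e-12):
            raise ConfigurationError(f"{name}: prevalence must be nonincreasing in birth year")
        self.values = values
        self.birth_year0 = int(birth_year0)
        self.name = name

    def lookup(self, birth_year):
        by = np.asarray(birth_year) - self.birth_year0
        if np.any(by < 0) or np.any(by >= len(self.values)):
            raise ConfigurationError(f"{self.name}: birth year outside covered range")
        return self.values[by]

    def to_frame(self) -> pd.DataFrame:
        years = self.birth_year0 + np.arange(len(self.values))
        return pd.DataFrame({"birth_year": years, "value": self.values})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "hp_prevalence") -> "BirthYearCurve":
        df = df.sort_values("birth_year")
        return cls(df["value"].to_numpy(), int(df["birth_year"].iloc[0]), name=name)


@dataclass
class RiskSchedules:
    """All exogenous risk schedules consumed by the cohort module."""

    hp_prevalence: BirthYearCurve
    smoking_initiation: Schedule3D
    smoking_cessation: Schedule3D
    lifetable: Schedule3D

    _FILES = {
        "smoking_initiation": "smoking_initiation.csv",
        "smoking_cessation": "smoking_cessation.csv",
        "lifetable": "lifetable.csv",
    }

    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.hp_prevalence.to_frame().to_csv(path / "hp_prevalence.csv", index=False)
        for attr, fname in self._FILES.items():
            getattr(self, attr).to_frame().to_csv(path / fname, index=False)

    @classmethod
    def from_dir(cls, path) -> "RiskSchedules":
        path = Path(path)
        kwargs = {}
        hp_file = path / "hp_prevalence.csv"
        if not hp_file.exists():
            raise ConfigurationError(f"missing schedule file {hp_file}")
        kwargs["hp_prevalence"] = BirthYearCurve.from_frame(pd.read_csv(hp_file))
        for attr, fname in cls._FILES.items():
            f = path / fname
            if not f.exists():
                raise ConfigurationError(f"missing schedule file {f}")
            kwargs[attr] = Schedule3D.from_frame(pd.read_csv(f), name=attr)
        return cls(**kwargs)


@dataclass
class Individual:
    """Scalar view of one simulated person (testing / inspection API)."""

    id: int
    sex: int
    birth_year: int
    age: int = AGE_ENTRY
    alive: bool = True
    cause_of_death: int = CAUSE_NONE
    health_state: HealthState = HealthState.NORMAL
    hp_infected: bool = False
    smoking: int = NEVER
    diagnosis: tuple[int, int] | None = None  # (stage, age at diagnosis)
    surveillance_years_left: int = 0
    discounted_cost: float = 0.0
    discounted_qaly: float = 0.0
    endoscopy_count: int = 0

    @property
    def year(self) -> int:
        # Calendar year of the current model cycle.
        return self.birth_year + self.age


class Population:
    """Struct-of-arrays container for the simulated cohort."""

    def __init__(self, sex, birth_year, hp_infected):
        n = len(sex)
        self.n = n
        self.sex = np.asarray(sex, dtype=np.int8)
        self.birth_year = np.asarray(birth_year, dtype=np.int16)
        self.hp_infected = np.asarray(hp_infected, dtype=bool)
        self.smoking = np.zeros(n, dtype=np.int8)
        self.state = np.zeros(n, dtype=np.int8)
        self.alive = np.ones(n, dtype=bool)
        self.cause = np.zeros(n, dtype=np.int8)
        self.diagnosed = np.zeros(n, dtype=bool)
        self.diag_stage = np.full(n, -1, dtype=np.int8)
        self.age_at_diagnosis = np.full(n, -1, dtype=np.int16)
        self.years_since_diagnosis = np.zeros(n, dtype=np.int16)
        self.surveillance_left = np.zeros(n, dtype=np.int8)
        self.recurrence_prob = np.zeros(n, dtype=float)
        self.endoscopies = np.zeros(n, dtype=np.int32)
        self.cost_disc = np.zeros(n, dtype=float)
        self.qaly_disc = np.zeros(n, dtype=float)
        self.qaly_undisc = np.zeros(n, dtype=float)
        self.age_at_death = np.full(n, -1, dtype=np.int16)

    def copy(self) -> "Population":
        new = Population.__new__(Population)
        new.n = self.n
        for k, v in self.__dict__.items():
            if isinstance(v, np.ndarray):
                setattr(new, k, v.copy())
            else:
                setattr(new, k, v)
        return new

    def individual(self, i: int) -> Individual:
        diag = None
        if self.diagnosed[i]:
            diag = (int(self.diag_stage[i]), int(self.age_at_diagnosis[i]))
        return Individual(
            id=i,
            sex=int(self.sex[i]),
            birth_year=int(self.birth_year[i]),
            alive=bool(self.alive[i]),
            cause_of_death=int(self.cause[i]),
            health_state=HealthState(int(self.state[i])),
            hp_infected=bool(self.hp_infected[i]),
            smoking=int(self.smoking[i]),
            diagnosis=diag,
            surveillance_years_left=int(self.surveillance_left[i]),
            discounted_cost=float(self.cost_disc[i]),
            discounted_qaly=float(self.qaly_disc[i]),
            endoscopy_count=int(self.endoscopies[i]),
        )


def create_population(
    n: int,
    schedules: RiskSchedules,
    seed: int | np.random.SeedSequence,
    birth_year_range: tuple[int, int] = (1965, 1985),
    sex_ratio: float = 0.5,
) -> Population:
    """Draw ``n`` individuals entering the model at age 20.

    Parameters
    ----------
    n
        Cohort size (>= 1).
    schedules
        Risk schedules; the *H. pylori* curve must cover ``birth_year_range``.
    seed
        Integer seed or a ``SeedSequence``; identical seeds give
        field-by-field identical populations.
    birth_year_range
        Inclusive birth-year interval, drawn uniformly.
    sex_ratio
        Probability of male sex.
    """
    if n < 1:
        raise ConfigurationError("population size must be >= 1")
    lo, hi = birth_year_range
    rng = np.random.default_rng(seed)
    sex = np.where(rng.random(n) < sex_ratio, MALE, FEMALE).astype(np.int8)
    birth_year = rng.integers(lo, hi + 1, size=n).astype(np.int16)
    p_hp = schedules.hp_prevalence.lookup(birth_year)
    hp = rng.random(n) < p_hp
    return Population(sex, birth_year, hp)


def update_smoking(ind: Individual, schedules: RiskSchedules, rng: np.random.Generator) -> Individual:
    """Advance one person's smoking status by one model year.

    Never-smokers may initiate; current smokers may quit (net cessation);
    former smokers never re-initiate.
    """
    if not ind.alive:
        raise ModelLogicError(f"individual {ind.id} is not alive")
    u = rng.random()
    if ind.smoking == NEVER:
        p = float(schedules.smoking_initiation.lookup(ind.age, ind.sex, ind.year))
        if u < p:
            ind.smoking = CURRENT
    elif ind.smoking == CURRENT:
        p = float(schedules.smoking_cessation.lookup(ind.age, ind.sex, ind.year))
        if u < p:
            ind.smoking = FORMER
    return ind


def other_cause_death(ind: Individual, schedules: RiskSchedules, rng: np.random.Generator) -> bool:
    """One annual draw against the period life table; sets cause on death."""
    if not ind.alive:
        raise ModelLogicError(f"individual {ind.id} is not alive")
    q = float(schedules.lifetable.lookup(ind.age, ind.sex, ind.year))
    if rng.random() < q:
        ind.alive = False
        ind.cause_of_death = CAUSE_OTHER
        return True
    return False
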