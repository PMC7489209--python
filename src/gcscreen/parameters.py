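"""Model input parameters: test characteristics, treatment outcomes,
costs, utilities, discounting, and the natural-history transition set.

The default values reproduce the published base-case inputs of the Japanese
national endoscopic screening evaluation (2015 US$, societal perspective).
Natural-history transition probabilities are *not* published inputs; they are
the calibrated unknowns, and the defaults here are synthetic fixture values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator

import yaml

DAY = 1.0 / 365.25
WEEK = 7.0 / 365.25
MONTH = 30.0 / 365.25


@dataclass
class TestCharacteristics:
    """Operating characteristics of a screening endoscopy with biopsy."""

    sensitivity: float = 0.886
    specificity: float = 0.851
    complication_prob: float = 0.0000195
    death_prob: float = 0.0000011

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")


@dataclass
class ProcedureOutcomes:
    """Outcome probabilities of a therapeutic procedure (ESD or gastrectomy)."""

    complete_resection: float
    complication: float
    death: float
    annual_recurrence: float

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name}={v} outside [0, 1]")


@dataclass
class TreatmentModel:
    """ESD for dysplasia and gastrectomy for (screen-detected local) cancer."""

    esd: ProcedureOutcomes = field(
        default_factory=lambda: ProcedureOutcomes(0.90, 0.0241927, 0.0001599, 0.014)
    )
    surgery: ProcedureOutcomes = field(
        default_factory=lambda: ProcedureOutcomes(1.0, 0.0615385, 0.0043956, 0.004)
    )


@dataclass
class CostSchedule:
    """Direct medical costs (2015 US$) and patient-time hours.

    Patient time is valued at the median hourly wage; indirect cost of an
    event = hours x hourly_wage.
    """

    endoscopy: float = 127.0
    esd: float = 1731.0
    complication_minor: float = 380.0
    complication_major: float = 852.0
    first_year: tuple[float, float, float] = (11110.0, 20645.0, 29610.0)
    subsequent_year: tuple[float, float, float] = (1544.0, 3171.0, 5655.0)
    terminal_year: float = 51497.0
    hours_endoscopy: float = 8.0
    hours_esd: float = 56.0
    hours_surgery: float = 136.0
    hours_first_year: float = 351.0
    hours_subsequent_year: float = 48.0
    hours_final_year: float = 512.0
    hourly_wage: float = 16.75

    @property
    def complication_expected(self) -> float:
        # Two published complication-management prices without a stated
        # split; minor and major are assumed equally likely.
        return 0.5 * (self.complication_minor + self.complication_major)


@dataclass
class UtilitySchedule:
    """Health-state utilities and procedure time-loss decrements.

    Decrement durations are years spent at utility zero; the loss is valued
    at the individual's current state utility.
    """

    local: float = 0.773
    regional: float = 0.590
    distant: float = 0.404
    healthy: float = 1.0
    endoscopy_days: float = 1.0
    endoscopy_complication_days: float = 7.0
    surgery_days: float = 14.0
    surgery_complication_days: float = 30.0

    def stage_utilities(self) -> tuple[float, float, float]:
        return (self.local, self.regional, self.distant)

    def decrement_years(self, event: str) -> float:
        days = {
            "endoscopy": self.endoscopy_days,
            "endoscopy_complication": self.endoscopy_complication_days,
            "surgery": self.surgery_days,
            "surgery_complication": self.surgery_complication_days,
        }[event]
        return days / 365.25


@dataclass
class DiscountSpec:
    rate_costs: float = 0.03
    rate_effects: float = 0.03
    reference_age: int = 20

    def __post_init__(self) -> None:
        if self.rate_costs < 0 or self.rate_effects < 0:
            raise ValueError("discount rates must be nonnegative")


@dataclass
class TransitionParameters:
    """Annual natural-history transition probabilities and risk multipliers.

    These are the calibrated unknowns of the model.  ``bounds`` carries the
    per-parameter search intervals used by the calibration harness.
    """

    p_normal_ag: float = 0.004
    p_ag_im: float = 0.03
    p_im_dys: float = 0.006
    p_dys_local: float = 0.04
    p_local_regional: float = 0.30
    p_regional_distant: float = 0.40
    s_local: float = 0.18
    s_regional: float = 0.40
    s_distant: float = 0.75
    rr_hp: float = 4.0
    rr_smoker_current: float = 2.0
    rr_smoker_former: float = 1.4
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    PROB_FIELDS = (
        "p_normal_ag",
        "p_ag_im",
        "p_im_dys",
        "p_dys_local",
        "p_local_regional",
        "p_regional_distant",
        "s_local",
        "s_regional",
        "s_distant",
    )
    RR_FIELDS = ("rr_hp", "rr_smoker_current", "rr_smoker_former")

    def __post_init__(self) -> None:
        for name in self.PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in self.RR_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"bounds for {name}: low {lo} > high {hi}")

    def replace(self, **kwargs: float) -> "TransitionParameters":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        d = {k: float(getattr(self, k)) for k in self.PROB_FIELDS + self.RR_FIELDS}
        d["bounds"] = {k: [float(lo), float(hi)] for k, (lo, hi) in self.bounds.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TransitionParameters":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        bounds = {k: (float(lo), float(hi)) for k, (lo, hi) in d.pop("bounds", {}).items()}
        return cls(bounds=bounds, **{k: float(v) for k, v in d.items()})


@dataclass
class ModelInputs:
    """Bundle of all non-natural-history inputs used by the engine."""

    test: TestCharacteristics = field(default_factory=TestCharacteristics)
    treatment: TreatmentModel = field(default_factory=TreatmentModel)
    costs: CostSchedule = field(default_factory=CostSchedule)
    utilities: UtilitySchedule = field(default_factory=UtilitySchedule)
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    adherence: float = 1.0  # perfect adherence in all published scenarios
    # Whether screen-detected local cancer is treated surgically (default)
    # rather than endoscopically.
    local_cancer_surgery: bool = True

    def with_param(self, name: str, value: float) -> "ModelInputs":
        """Return a deep copy with one registry parameter replaced."""
        spec = PARAMETER_REGISTRY[name]
        new = dataclasses.replace(
            self,
            test=dataclasses.replace(self.test),
            treatment=TreatmentModel(
                esd=dataclasses.replace(self.treatment.esd),
                surgery=dataclasses.replace(self.treatment.surgery),
            ),
            costs=dataclasses.replace(self.costs),
            utilities=dataclasses.replace(self.utilities),
            discount=dataclasses.replace(self.discount),
        )
        obj = new
        for attr in spec.path[:-1]:
            obj = getattr(obj, attr)
        setattr(obj, spec.path[-1], value)
        return new

    def get_param(self, name: str) -> float:
        obj = self
        for attr in PARAMETER_REGISTRY[name].path:
            obj = getattr(obj, attr)
        return obj


@dataclass(frozen=True)
class ParamSpec:
    """Registry entry: base value, one-way range, and PSA distribution family."""

    name: str
    path: tuple[str, ...]
    base: float
    family: str  # beta | gamma | fixed
    low: float | None = None  # one-way / 95% uncertainty bounds
    high: float | None = None

    def oneway_range(self) -> tuple[float, float]:
        if self.low is None or self.high is None:
            # parameters without a published range are varied by +/-20%
            return (0.8 * self.base, 1.2 * self.base)
        return (self.low, self.high)


def _specs() -> Iterator[ParamSpec]:
    yield ParamSpec("endoscopy_sensitivity", ("test", "sensitivity"), 0.886, "beta", 0.6982, 0.976)
    yield ParamSpec("endoscopy_specificity", ("test", "specificity"), 0.851, "beta", 0.8430, 0.859)
    yield ParamSpec("endoscopy_complication", ("test", "complication_prob"), 0.0000195, "beta")
    yield ParamSpec("endoscopy_death", ("test", "death_prob"), 0.0000011, "beta")
    yield ParamSpec("esd_complete_resection", ("treatment", "esd", "complete_resection"), 0.90, "beta", 0.8, 1.0)
    yield ParamSpec("esd_complication", ("treatment", "esd", "complication"), 0.0241927, "beta")
    yield ParamSpec("esd_death", ("treatment", "esd", "death"), 0.0001599, "beta")
    yield ParamSpec("esd_recurrence", ("treatment", "esd", "annual_recurrence"), 0.014, "beta")
    yield ParamSpec("surgery_complete_resection", ("treatment", "surgery", "complete_resection"), 1.0, "fixed")
    yield ParamSpec("surgery_complication", ("treatment", "surgery", "complication"), 0.0615385, "beta")
    yield ParamSpec("surgery_death", ("treatment", "surgery", "death"), 0.0043956, "beta")
    yield ParamSpec("surgery_recurrence", ("treatment", "surgery", "annual_recurrence"), 0.004, "beta")
    yield ParamSpec("cost_endoscopy", ("costs", "endoscopy"), 127.0, "gamma", 90.0, 160.0)
    yield ParamSpec("cost_esd", ("costs", "esd"), 1731.0, "gamma", 1400.0, 2000.0)
    yield ParamSpec("cost_complication_minor", ("costs", "complication_minor"), 380.0, "gamma", 250.0, 450.0)
    yield ParamSpec("cost_complication_major", ("costs", "complication_major"), 852.0, "gamma", 700.0, 1000.0)
    yield ParamSpec("cost_terminal", ("costs", "terminal_year"), 51497.0, "gamma")
    # discount-rate variants are one-way scenarios, never PSA-sampled
    yield ParamSpec("discount_rate_costs", ("discount", "rate_costs"), 0.03, "fixed", 0.035, 0.06)
    yield ParamSpec("discount_rate_effects", ("discount", "rate_effects"), 0.03, "fixed", 0.0, 0.015)


PARAMETER_REGISTRY: dict[str, ParamSpec] = {s.name: s for s in _specs()}

# Stage cost rows live in (local, regional, distant) tuples; they are set
# through apply_param below rather than an attribute path.
STAGE_COST_SPECS: dict[str, ParamSpec] = {
    "cost_local_first": ParamSpec("cost_local_first", ("costs", "first_year"), 11110.0, "gamma", 8000.0, 14000.0),
    "cost_regional_first": ParamSpec("cost_regional_first", ("costs", "first_year"), 20645.0, "gamma", 15000.0, 25000.0),
    "cost_distant_first": ParamSpec("cost_distant_first", ("costs", "first_year"), 29610.0, "gamma", 25000.0, 35000.0),
    "cost_local_subsequent": ParamSpec("cost_local_subsequent", ("costs", "subsequent_year"), 1544.0, "gamma"),
    "cost_regional_subsequent": ParamSpec("cost_regional_subsequent", ("costs", "subsequent_year"), 3171.0, "gamma"),
    "cost_distant_subsequent": ParamSpec("cost_distant_subsequent", ("costs", "subsequent_year"), 5655.0, "gamma"),
}

ALL_PARAM_SPECS: dict[str, ParamSpec] = {**PARAMETER_REGISTRY, **STAGE_COST_SPECS}

_STAGE_INDEX = {"local": 0, "regional": 1, "distant": 2}


def apply_param(inputs: ModelInputs, name: str, value: float) -> ModelInputs:
    """Return a copy of ``inputs`` with the named registry parameter set."""
    if name in PARAMETER_REGISTRY:
        return inputs.with_param(name, value)
    if name in STAGE_COST_SPECS:
        spec = STAGE_COST_SPECS[name]
        new = inputs.with_param("cost_endoscopy", inputs.costs.endoscopy)  # deep copy
        stage = _STAGE_INDEX[name.split("_")[1]]
        attr = spec.path[-1]
        row = list(getattr(new.costs, attr))
        row[stage] = value
        setattr(new.costs, attr, tuple(row))
        return new
    raise KeyError(f"unknown parameter {name!r}")
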