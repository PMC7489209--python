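"""Per-year cost and quality-of-life accounting (societal perspective).

Direct medical costs and patient-time (indirect) costs are accrued per
event and per treatment phase; quality-adjusted life-years weight each year
lived by a health-state utility, minus short procedure-related time losses
valued at the state utility.  Everything is discounted to model entry (age
20) at annual rates.
"""

from __future__ import annotations

from .cohort import Individual
from .errors import ConfigurationError, ModelLogicError
from .parameters import CostSchedule, UtilitySchedule

#: Recognised event codes.  A ``*_complication`` event stands for the whole
#: procedure including its complication, so it carries the procedure's
#: direct cost and hours plus complication management, and the longer
#: utility decrement.  Gastrectomy has no separate direct price: its direct
#: medical cost is carried by the stage treatment-phase costs.
_EVENTS: dict[str, tuple[tuple[str, ...], str, str]] = {
    "endoscopy": (("endoscopy",), "hours_endoscopy", "endoscopy"),
    "endoscopy_complication": (("endoscopy", "complication_expected"), "hours_endoscopy", "endoscopy_complication"),
    "esd": (("esd",), "hours_esd", "surgery"),
    "esd_complication": (("esd", "complication_expected"), "hours_esd", "surgery_complication"),
    "surgery": ((), "hours_surgery", "surgery"),
    "surgery_complication": (("complication_expected",), "hours_surgery", "surgery_complication"),
}


def discount(amount: float, years_since_reference: float, rate: float) -> float:
    """Present value at model entry: amount / (1 + rate)^years."""
    if years_since_reference < 0:
        raise ModelLogicError("cannot discount a negative number of years")
    return amount / (1.0 + rate) ** years_since_reference


def event_decrement_years(events: list[str], utilities: UtilitySchedule) -> float:
    """Total time (in years) lost to procedures this year.

    A complicated procedure replaces the uncomplicated decrement: callers
    pass either ``"endoscopy"`` or ``"endoscopy_complication"``, not both.
    """
    total = 0.0
    for ev in events:
        if ev not in _EVENTS:
            raise ConfigurationError(f"unknown event {ev!r}")
        total += utilities.decrement_years(_EVENTS[ev][2])
    return total


def annual_qaly(ind: Individual, utilities: UtilitySchedule, events: list[str] | None = None) -> float:
    """QALY increment for one year lived (undiscounted).

    The state utility (1.0 while free of diagnosed cancer, the stage utility
    from diagnosis onward) applies for the whole year, minus event time
    losses valued at that same utility.  Never negative.
    """
    events = events or []
    if ind.diagnosis is not None:
        u = utilities.stage_utilities()[ind.diagnosis[0]]
    else:
        u = utilities.healthy
    q = u * (1.0 - event_decrement_years(events, utilities))
    return max(0.0, q)


def annual_cost(
    ind: Individual,
    costs: CostSchedule,
    events: list[str] | None = None,
    dying_of_gc: bool = False,
) -> tuple[float, float]:
    """(direct, indirect) cost increment for one year (undiscounted).

    Procedure events price their direct cost plus patient-time hours.  A
    diagnosed cancer adds its phase cost: first-year cost in the year of
    diagnosis, subsequent-year cost thereafter, and the terminal-care cost
    (with final-year hours) replacing both in the year of gastric-cancer
    death.
    """
    events = events or []
    direct = 0.0
    hours = 0.0
    for ev in events:
        if ev not in _EVENTS:
            raise ConfigurationError(f"unknown event {ev!r} has no price")
        cost_attrs, hours_attr, _ = _EVENTS[ev]
        for attr in cost_attrs:
            direct += getattr(costs, attr)
        hours += getattr(costs, hours_attr)
    if ind.diagnosis is not None:
        stage, age_dx = ind.diagnosis
        if dying_of_gc:
            direct += costs.terminal_year
            hours += costs.hours_final_year
        elif ind.age == age_dx:
            direct += costs.first_year[stage]
            hours += costs.hours_first_year
        else:
            direct += costs.subsequent_year[stage]
            hours += costs.hours_subsequent_year
    return direct, hours * costs.hourly_wage
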