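"""Synthetic model inputs: every schedule the simulation needs that is not
a published table, generated with the statistical structure the analysis
assumes.

The generator emulates, not reproduces, the Japanese setting: a logistic
birth-cohort decline in *H. pylori* prevalence, Gompertz–Makeham period
life tables by sex, age/sex smoking initiation and net cessation schedules,
stage- and sex-specific post-diagnosis survival hazards, and a ground-truth
natural-history parameter set.  All outputs are deterministic functions of
the configuration; files written to disk are labelled NON-AUTHORITATIVE.

Calibration targets are produced by simulating the no-screening scenario
under the ground truth and summarising incidence, so parameter-recovery
experiments have a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import CalibrationTarget
from .cohort import BirthYearCurve, RiskSchedules, Schedule3D
from .errors import ConfigurationError
from .natural_history import SurvivalModel
from .parameters import ModelInputs, TransitionParameters

AGE0, AGE1 = 20, 100
BIRTH0, BIRTH1 = 1908, 2003


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic input generator (all deterministic)."""

    seed: int = 0
    # H. pylori prevalence: logistic decline between plateaus across birth years
    hp_high: float = 0.85
    hp_low: float = 0.10
    hp_midpoint_year: float = 1955.0
    hp_slope: float = 0.10
    # Gompertz-Makeham lifetable q(age) = makeham + A * exp(B * age), per sex
    gompertz_a: tuple[float, float] = (2.5e-5, 1.3e-5)
    gompertz_b: float = 0.095
    makeham: float = 2.5e-4
    # smoking schedules
    initiation_20s: tuple[float, float] = (0.035, 0.012)
    initiation_30s: tuple[float, float] = (0.015, 0.006)
    cessation_young: float = 0.03
    cessation_old: float = 0.06
    # post-diagnosis annual gastric-cancer death hazards, years 1..n then constant
    survival_local: tuple[float, ...] = (0.03, 0.025, 0.02, 0.015, 0.01, 0.005)
    survival_regional: tuple[float, ...] = (0.22, 0.18, 0.14, 0.10, 0.07, 0.03)
    survival_distant: tuple[float, ...] = (0.55, 0.45, 0.35, 0.25, 0.20, 0.10)
    female_hazard_ratio: float = 0.9
    ground_truth: TransitionParameters = field(default_factory=TransitionParameters)


def _hp_curve(cfg: SyntheticConfig) -> BirthYearCurve:
    years = np.arange(BIRTH0, BIRTH1 + 1)
    logistic = 1.0 / (1.0 + np.exp(cfg.hp_slope * (years - cfg.hp_midpoint_year)))
    values = cfg.hp_low + (cfg.hp_high - cfg.hp_low) * logistic
    return BirthYearCurve(values, BIRTH0)


def _lifetable(cfg: SyntheticConfig) -> Schedule3D:
    ages = np.arange(AGE0, AGE1 + 1)
    year0, nyears = 1985, 2  # schedules are flat in calendar year
    values = np.zeros((len(ages), 2, nyears))
    for sex in (0, 1):
        q = cfg.makeham + cfg.gompertz_a[sex] * np.exp(cfg.gompertz_b * ages)
        values[:, sex, :] = np.minimum(1.0, q)[:, None]
    return Schedule3D(values, AGE0, year0, name="lifetable")


def _smoking(cfg: SyntheticConfig) -> tuple[Schedule3D, Schedule3D]:
    ages = np.arange(AGE0, AGE1 + 1)
    year0, nyears = 1985, 2
    init = np.zeros((len(ages), 2, nyears))
    cess = np.zeros((len(ages), 2, nyears))
    for sex in (0, 1):
        p = np.where(ages < 30, cfg.initiation_20s[sex], np.where(ages < 40, cfg.initiation_30s[sex], 0.0))
        init[:, sex, :] = p[:, None]
        c = np.where(ages < 50, cfg.cessation_young, cfg.cessation_old)
        cess[:, sex, :] = c[:, None]
    return (
        Schedule3D(init, AGE0, year0, name="smoking_initiation"),
        Schedule3D(cess, AGE0, year0, name="smoking_cessation"),
    )


def _survival(cfg: SyntheticConfig) -> SurvivalModel:
    local = np.asarray(cfg.survival_local)
    regional = np.asarray(cfg.survival_regional)
    distant = np.asarray(cfg.survival_distant)
    if not (len(local) == len(regional) == len(distant)):
        raise ConfigurationError("survival hazard vectors must share a length")
    if np.any(distant < local) or np.any(regional < local) or np.any(distant < regional):
        raise ConfigurationError(
            "survival hazards must be stage-ordered (distant >= regional >= local) year by year"
        )
    hz = np.stack([local, regional, distant])  # (3 stages, n_years)
    hazard = np.stack([hz, cfg.female_hazard_ratio * hz])  # (2 sexes, 3, n_years)
    return SurvivalModel(np.clip(hazard, 0.0, 1.0))


def make_fixtures(
    config: SyntheticConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[RiskSchedules, SurvivalModel, TransitionParameters]:
    """Build (and optionally write) the complete synthetic input bundle.

    Writing is refused, with the offending field named, if any generated
    schedule violates its invariants (probability range, monotone *H.
    pylori* decline, stage ordering of survival hazards) — the container
    constructors enforce these.
    """
    cfg = config if config is not None else SyntheticConfig()
    init, cess = _smoking(cfg)
    schedules = RiskSchedules(
        hp_prevalence=_hp_curve(cfg),
        smoking_initiation=init,
        smoking_cessation=cess,
        lifetable=_lifetable(cfg),
    )
    survival = _survival(cfg)
    truth = cfg.ground_truth
    if not truth.bounds:
        truth = truth.replace(
            bounds={
                name: (0.5 * getattr(truth, name), min(1.0, 2.0 * getattr(truth, name)))
                for name in TransitionParameters.PROB_FIELDS
            }
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        schedules.to_dir(out_dir)
        survival.to_csv(out_dir / "survival.csv")
        truth.to_yaml(out_dir / "transition_params.yaml")
        (out_dir / "README.txt").write_text(
            "NON-AUTHORITATIVE synthetic fixtures generated by gcscreen.synthetic_data.\n"
            "These emulate the statistical shape of the Japanese inputs (birth-cohort\n"
            "H. pylori decline, period life tables, smoking schedules, stage-specific\n"
            "survival) but encode no observed registry or survey values.\n"
        )
    return schedules, survival, truth


def make_calibration_targets(
    ground_truth: TransitionParameters,
    n_individuals: int,
    seed: int,
    config: SyntheticConfig | None = None,
    inputs: ModelInputs | None = None,
) -> CalibrationTarget:
    """Simulate the no-screening scenario under known ground truth and
    summarise it as calibration targets (rates carry sampling noise)."""
    from .engine import Simulator  # local import to avoid a cycle

    if n_individuals < 10_000:
        raise ConfigurationError("calibration targets need at least 10^4 individuals")
    cfg = config if config is not None else SyntheticConfig()
    schedules, survival, _ = make_fixtures(cfg)
    sim = Simulator(schedules, survival, ground_truth, inputs)
    rates, stage_dist = sim.incidence_summary(n_individuals, seed)
    return CalibrationTarget(incidence=rates, stage_distribution=stage_dist)
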