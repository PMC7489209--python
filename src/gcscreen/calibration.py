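"""Random-search least-squares calibration of the natural-history
parameters to age/sex incidence and stage-distribution targets.

Candidate parameter sets are drawn independently and uniformly within
per-parameter search bounds (Latin-hypercube sampling is available behind a
flag), each candidate is scored by simulating the no-screening scenario and
summing squared deviations from the targets, and the best ``k`` sets are
retained; their per-parameter min–max envelope serves as the uncertainty
interval for model outputs.

Every candidate is simulated with the same seed (common random numbers), so
score differences reflect parameters rather than Monte-Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .parameters import TransitionParameters


@dataclass
class CalibrationTarget:
    """Incidence rates per 100,000 person-years by (age group, sex) and the
    stage distribution of diagnosed cancers by sex.

    Weights are unitless multipliers on the squared deviation of each
    component; stage proportions enter in percentage points so the two
    components share a rough scale.
    """

    incidence: pd.DataFrame  # columns: age_group, sex, rate_per_100k
    stage_distribution: pd.DataFrame  # columns: sex, stage, proportion
    incidence_weight: float = 1.0
    stage_weight: float = 1.0

    def __post_init__(self) -> None:
        rates = self.incidence["rate_per_100k"]
        if (rates.dropna() < 0).any():
            raise ConfigurationError("incidence rates must be nonnegative")
        sums = self.stage_distribution.groupby("sex")["proportion"].sum(min_count=1)
        for sex, s in sums.items():
            if not np.isnan(s) and abs(s - 1.0) > 1e-6:
                raise ConfigurationError(f"stage proportions for sex={sex} sum to {s}, not 1")


@dataclass
class CalibrationResult:
    samples: pd.DataFrame  # one row per candidate: parameters + score, score-ascending
    top_k: pd.DataFrame
    envelope: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def best(self) -> pd.Series:
        return self.samples.iloc[0]

    def best_parameters(self, template: TransitionParameters) -> TransitionParameters:
        values = {k: float(self.best[k]) for k in self.samples.columns if k != "score"}
        return template.replace(**values)


def sample_parameter_sets(
    bounds: dict[str, tuple[float, float]],
    n_search: int,
    seed: int | np.random.SeedSequence,
    method: str = "uniform",
) -> pd.DataFrame:
    """Draw ``n_search`` candidate parameter sets within ``bounds``."""
    if not bounds:
        raise ConfigurationError("no search bounds given")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names])
    hi = np.array([bounds[k][1] for k in names])
    if np.any(lo > hi) or not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise ConfigurationError("bounds must be finite with low <= high")
    if method == "uniform":
        rng = np.random.default_rng(seed)
        u = rng.random((n_search, len(names)))
    elif method == "lhs":
        from scipy.stats import qmc

        ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
        sampler = qmc.LatinHypercube(d=len(names), seed=np.random.default_rng(ss))
        u = sampler.random(n_search)
    else:
        raise ConfigurationError(f"unknown sampling method {method!r}")
    return pd.DataFrame(lo + u * (hi - lo), columns=names)


def _merge_model_to_target(target_df, model_df, on, value):
    merged = target_df.merge(model_df, on=on, suffixes=("_target", "_model"), how="left")
    t = merged[f"{value}_target"].to_numpy(dtype=float)
    m = merged[f"{value}_model"].to_numpy(dtype=float)
    keep = ~np.isnan(t)
    # an empty model stratum facing a nonzero target counts as zero output,
    # contributing target^2 rather than being skipped
    m = np.where(np.isnan(m), 0.0, m)
    return t[keep], m[keep]


def score_from_summaries(
    rates: pd.DataFrame,
    stage_dist: pd.DataFrame,
    target: CalibrationTarget,
) -> float:
    """Weighted sum of squares between model summaries and targets."""
    t, m = _merge_model_to_target(target.incidence, rates, ["age_group", "sex"], "rate_per_100k")
    score = target.incidence_weight * float(np.sum((m - t) ** 2))
    t, m = _merge_model_to_target(
        target.stage_distribution, stage_dist, ["sex", "stage"], "proportion"
    )
    score += target.stage_weight * float(np.sum((100.0 * (m - t)) ** 2))
    return score


def score_parameter_set(
    params: TransitionParameters,
    target: CalibrationTarget,
    schedules,
    survival,
    n_individuals: int,
    seed: int,
    inputs=None,
) -> float:
    """Simulate the no-screening scenario under ``params`` and score it."""
    from .engine import Simulator

    sim = Simulator(schedules, survival, params, inputs)
    rates, stage_dist = sim.incidence_summary(n_individuals, seed)
    return score_from_summaries(rates, stage_dist, target)


def calibrate(
    bounds: dict[str, tuple[float, float]],
    target: CalibrationTarget,
    schedules,
    survival,
    n_search: int,
    n_individuals: int,
    k: int = 50,
    seed: int = 0,
    template: TransitionParameters | None = None,
    method: str = "uniform",
    inputs=None,
    progress: bool = False,
) -> CalibrationResult:
    """Score ``n_search`` uniform draws and keep the ``k`` best.

    Deterministic given ``seed``: one child seed drives the candidate draws
    and a second, fixed child seed drives every candidate's simulation.
    """
    if k > n_search:
        raise ConfigurationError("k cannot exceed n_search")
    template = template if template is not None else TransitionParameters()
    root = np.random.SeedSequence(seed)
    draw_ss, sim_ss = root.spawn(2)
    sim_seed = int(sim_ss.generate_state(1)[0] % (2**31))
    candidates = sample_parameter_sets(bounds, n_search, draw_ss, method=method)
    scores = np.empty(n_search)
    iterator = candidates.iterrows()
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator, total=n_search)
        except ImportError:
            pass
    for i, row in iterator:
        params = template.replace(**{name: float(v) for name, v in row.items()})
        scores[i] = score_parameter_set(
            params, target, schedules, survival, n_individuals, sim_seed, inputs
        )
    samples = candidates.assign(score=scores).sort_values("score", kind="stable").reset_index(drop=True)
    top_k = samples.head(k)
    envelope = {
        name: (float(top_k[name].min()), float(top_k[name].max())) for name in candidates.columns
    }
    return CalibrationResult(samples=samples, top_k=top_k, envelope=envelope)
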