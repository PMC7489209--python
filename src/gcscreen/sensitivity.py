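"""One-way (tornado) and probabilistic sensitivity analysis.

One-way analysis reruns the comparison of interest (by default the 50-75-3
strategy against no screening) with a single parameter at each end of its
uncertainty range, everything else at base case.

The probabilistic analysis is second-order Monte Carlo: each of ``n_draws``
replications samples all uncertain inputs jointly-independently from
method-of-moments beta/gamma distributions (the published one-way range is
read as a 95% interval; parameters without a range use ±20% of the base
value), reruns the scaled simulation with common random numbers, and
records the incremental cost and QALYs against no screening.  The
cost-effectiveness acceptability curve is the fraction of draws with
positive net monetary benefit at each willingness-to-pay value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .parameters import ALL_PARAM_SPECS, apply_param
from .screening import ScreeningStrategy


@dataclass
class DistributionSpec:
    """Uncertainty distribution of one input parameter."""

    name: str
    family: str  # beta | gamma | fixed
    base: float
    low: float | None = None
    high: float | None = None
    fitted: tuple[float, ...] = ()

    @classmethod
    def from_registry(cls, name: str) -> "DistributionSpec":
        spec = ALL_PARAM_SPECS[name]
        lo, hi = spec.oneway_range()
        return cls(name=name, family=spec.family, base=spec.base, low=lo, high=hi)


def fit_distribution(spec: DistributionSpec) -> DistributionSpec:
    """Method-of-moments fit: mean = base, SD = (high - low) / (2 * 1.96).

    Returns a copy with ``fitted`` set: (alpha, beta) for beta, (shape,
    scale) for gamma, () for fixed.  Raises when the moments are infeasible
    for the family, naming the parameter.
    """
    if spec.family == "fixed":
        return DistributionSpec(**{**spec.__dict__, "fitted": ()})
    if spec.low is None or spec.high is None:
        raise ConfigurationError(f"{spec.name}: no range to fit a {spec.family} distribution")
    m = spec.base
    sd = (spec.high - spec.low) / (2.0 * 1.96)
    if sd <= 0:
        raise ConfigurationError(f"{spec.name}: degenerate range for {spec.family} fit")
    v = sd * sd
    if spec.family == "beta":
        if not 0.0 < m < 1.0:
            raise ConfigurationError(f"{spec.name}: beta mean {m} must lie in (0, 1)")
        if v >= m * (1.0 - m):
            raise ConfigurationError(f"{spec.name}: variance too large for a beta with mean {m}")
        k = m * (1.0 - m) / v - 1.0
        fitted = (m * k, (1.0 - m) * k)
    elif spec.family == "gamma":
        if m <= 0:
            raise ConfigurationError(f"{spec.name}: gamma mean must be positive")
        fitted = (m * m / v, v / m)  # (shape, scale)
    else:
        raise ConfigurationError(f"{spec.name}: unknown family {spec.family!r}")
    return DistributionSpec(**{**spec.__dict__, "fitted": fitted})


def sample_spec(spec: DistributionSpec, rng: np.random.Generator) -> float:
    if spec.family == "fixed":
        return spec.base
    if not spec.fitted:
        spec = fit_distribution(spec)
    if spec.family == "beta":
        return float(rng.beta(*spec.fitted))
    return float(rng.gamma(*spec.fitted))


def default_psa_specs() -> list[DistributionSpec]:
    """Fitted distributions for every registry input marked beta or gamma."""
    out = []
    for name, spec in ALL_PARAM_SPECS.items():
        if spec.family in ("beta", "gamma"):
            out.append(fit_distribution(DistributionSpec.from_registry(name)))
    return out


def _incremental(simulator, strategy, n, seed):
    """Per-1000 (Δcost $, ΔQALY) of ``strategy`` vs no screening, CRN."""
    root = np.random.SeedSequence(seed)
    pop = simulator.make_population(n, root.spawn(1)[0])
    ref = simulator.simulate_strategy(None, population=pop, seed_seq=np.random.SeedSequence(seed))
    scr = simulator.simulate_strategy(strategy, population=pop, seed_seq=np.random.SeedSequence(seed))
    dcost = 1000.0 * (scr.cost_disc - ref.cost_disc) / n
    dqaly = 1000.0 * (scr.qalys_disc - ref.qalys_disc) / n
    return dcost, dqaly


def one_way(
    name: str,
    simulator,
    strategy: ScreeningStrategy | None = None,
    n: int = 20_000,
    seed: int = 0,
    low: float | None = None,
    high: float | None = None,
) -> tuple[float, float]:
    """ICER of ``strategy`` vs no screening at each end of one parameter's range.

    Returns (icer_at_low, icer_at_high) for tornado ordering.
    """
    from .engine import Simulator

    spec = ALL_PARAM_SPECS[name]
    lo, hi = spec.oneway_range()
    lo = lo if low is None else low
    hi = hi if high is None else high
    if lo > hi:
        raise ConfigurationError(f"{name}: low {lo} > high {hi}")
    strategy = strategy if strategy is not None else ScreeningStrategy(50, 75, 3)
    icers = []
    for value in (lo, hi):
        inputs = apply_param(simulator.inputs, name, value)
        sim = Simulator(simulator.schedules, simulator.survival, simulator.params, inputs)
        dcost, dqaly = _incremental(sim, strategy, n, seed)
        if dqaly <= 0:
            raise ConfigurationError(f"{name}={value}: strategy gains no QALYs; ICER undefined")
        icers.append(dcost / dqaly)
    return icers[0], icers[1]


def tornado(
    names: list[str],
    simulator,
    strategy: ScreeningStrategy | None = None,
    n: int = 20_000,
    seed: int = 0,
) -> pd.DataFrame:
    """One-way ICERs for several parameters, widest bar first."""
    rows = []
    for name in names:
        lo_icer, hi_icer = one_way(name, simulator, strategy, n, seed)
        rows.append({"parameter": name, "icer_low": lo_icer, "icer_high": hi_icer})
    df = pd.DataFrame(rows)
    df["width"] = (df["icer_high"] - df["icer_low"]).abs()
    return df.sort_values("width", ascending=False).reset_index(drop=True)


@dataclass
class PSAResult:
    cloud: pd.DataFrame  # columns: draw, dcost, dqaly (per 1000)
    ceac: pd.DataFrame  # columns: wtp, probability
    parameter_draws: pd.DataFrame

    def ceac_at(self, wtp: float) -> float:
        i = int(np.argmin(np.abs(self.ceac["wtp"].to_numpy() - wtp)))
        return float(self.ceac["probability"].iloc[i])


def run_psa(
    n_draws: int,
    specs: list[DistributionSpec],
    simulator,
    strategy: ScreeningStrategy | None = None,
    wtp_grid: np.ndarray | None = None,
    seed: int = 0,
    n_individuals: int = 10_000,
    progress: bool = False,
) -> PSAResult:
    """Second-order probabilistic sensitivity analysis with a CEAC.

    The same simulation seed is reused for every draw, so the scatter of
    the incremental cloud reflects parameter uncertainty only.
    """
    from .engine import Simulator

    if wtp_grid is None:
        wtp_grid = np.arange(0, 200_001, 10_000, dtype=float)
    strategy = strategy if strategy is not None else ScreeningStrategy(50, 75, 3)
    root = np.random.SeedSequence(seed)
    param_ss, sim_ss = root.spawn(2)
    param_rng = np.random.default_rng(param_ss)
    sim_seed = int(sim_ss.generate_state(1)[0] % (2**31))
    rows, draws = [], []
    iterator = range(n_draws)
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(iterator)
        except ImportError:
            pass
    for d in iterator:
        values = {spec.name: sample_spec(spec, param_rng) for spec in specs}
        inputs = simulator.inputs
        for name, value in values.items():
            inputs = apply_param(inputs, name, value)
        sim = Simulator(simulator.schedules, simulator.survival, simulator.params, inputs)
        dcost, dqaly = _incremental(sim, strategy, n_individuals, sim_seed)
        rows.append({"draw": d, "dcost": dcost, "dqaly": dqaly})
        draws.append(values)
    cloud = pd.DataFrame(rows)
    nmb_ok = [
        [(row["dqaly"] * w - row["dcost"]) >= 0 for _, row in cloud.iterrows()] for w in wtp_grid
    ]
    ceac = pd.DataFrame(
        {"wtp": wtp_grid, "probability": [float(np.mean(col)) for col in nmb_ok]}
    )
    return PSAResult(cloud=cloud, ceac=ceac, parameter_draws=pd.DataFrame(draws))
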