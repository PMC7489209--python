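"""Cost-effectiveness analysis: dominance, the efficient frontier,
incremental cost-effectiveness ratios, and the willingness-to-pay decision.

Strategies are ranked by increasing cost.  A strategy is *strongly*
dominated if another strategy costs no more and yields at least as many
QALYs; it is removed by *extended* dominance if its ICER exceeds that of a
more effective strategy (a mixture of its neighbours would beat it).  ICERs
are computed only along the remaining frontier, where they are strictly
increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError


@dataclass
class CEAEntry:
    strategy: str
    cost: float  # per-1000, $1000s (any consistent basis works)
    qaly: float  # per-1000 QALYs (gained or absolute; consistent basis)
    dominated: bool = False
    dominance_type: str = "none"  # none | strong | extended
    icer: float | None = None  # $ per QALY vs frontier predecessor


@dataclass
class CEATable:
    """Rows sorted by increasing cost; ICERs only on frontier rows."""

    entries: list[CEAEntry]

    @property
    def frontier(self) -> list[CEAEntry]:
        return [e for e in self.entries if not e.dominated]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": e.strategy,
                    "cost": e.cost,
                    "qaly": e.qaly,
                    "dominated": e.dominated,
                    "dominance_type": e.dominance_type,
                    "icer": e.icer,
                }
                for e in self.entries
            ]
        )


def compute_icer(
    more_effective: tuple[float, float],
    comparator: tuple[float, float],
    cost_scale: float = 1.0,
) -> float:
    """Incremental cost per QALY gained between two (cost, qaly) points.

    ``cost_scale`` converts the cost units to dollars (1000.0 when costs are
    tabulated in $1000s).  A non-positive QALY difference has no defined
    ICER and must be handled as dominance by the caller.
    """
    dc = (more_effective[0] - comparator[0]) * cost_scale
    dq = more_effective[1] - comparator[1]
    if dq <= 0:
        raise ConfigurationError("ICER undefined for non-positive QALY difference")
    return dc / dq


def find_frontier(
    strategies: list[str],
    costs: np.ndarray | list[float],
    qalys: np.ndarray | list[float],
    cost_scale: float = 1.0,
) -> CEATable:
    """Apply strong then extended dominance and compute frontier ICERs.

    Equal-cost ties are ordered by descending QALY and the worse duplicate
    is marked strongly dominated.  Requires at least two strategies (one of
    them the cheapest anchor, typically no screening).
    """
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    if len(strategies) < 2:
        raise ConfigurationError("need at least two strategies for a frontier")
    order = np.lexsort((-qalys, costs))  # cost asc, then qaly desc
    entries = [CEAEntry(strategies[i], float(costs[i]), float(qalys[i])) for i in order]

    # strong dominance: a no-more-costly strategy with >= QALYs exists
    best_q = -np.inf
    for e in entries:
        if e.qaly <= best_q:
            e.dominated = True
            e.dominance_type = "strong"
        else:
            best_q = e.qaly

    # extended dominance: prune until ICERs strictly increase along the chain
    changed = True
    while changed:
        changed = False
        chain = [e for e in entries if not e.dominated]
        icers = [
            compute_icer((b.cost, b.qaly), (a.cost, a.qaly), cost_scale)
            for a, b in zip(chain[:-1], chain[1:])
        ]
        for i in range(len(icers) - 1):
            # <= : a collinear middle point adds nothing at the same price
            # per QALY and is pruned so frontier ICERs strictly increase
            if icers[i + 1] <= icers[i]:
                chain[i + 1].dominated = True
                chain[i + 1].dominance_type = "extended"
                changed = True
                break

    chain = [e for e in entries if not e.dominated]
    for a, b in zip(chain[:-1], chain[1:]):
        b.icer = compute_icer((b.cost, b.qaly), (a.cost, a.qaly), cost_scale)
    return CEATable(entries)


def optimal_strategy(table: CEATable, wtp: float) -> str:
    """Highest-QALY frontier strategy whose ICER does not exceed ``wtp``.

    The cheapest frontier strategy (no ICER) always qualifies, so the
    answer falls back to the anchor when nothing is worth buying.
    """
    best = None
    for e in table.frontier:
        if e.icer is None or e.icer <= wtp:
            if best is None or e.qaly > best.qaly:
                best = e
    assert best is not None  # frontier is never empty
    return best.strategy


def cea_from_outcomes(df: pd.DataFrame) -> CEATable:
    """Build the CEA table from a ``run_all``-style outcome frame."""
    return find_frontier(
        df["strategy"].tolist(),
        df["cost_per_1000_thousands"].to_numpy(),
        df["qalys_gained_per_1000"].to_numpy(),
        cost_scale=1000.0,
    )
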