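"""Independent brute-force constructions used to cross-check the CEA code."""

import numpy as np


def frontier_oracle(costs, qalys) -> set[int]:
    """Efficient frontier by greedy gift-wrapping on the (cost, QALY) plane.

    Starting from the cheapest strategy, repeatedly move to the strategy
    with the smallest incremental cost-effectiveness ratio among all
    strictly more effective ones.  This traces the vertices of the
    upper-left convex hull and is an independent construction from the
    iterative dominance-pruning in the package.
    """
    costs = np.asarray(costs, dtype=float)
    qalys = np.asarray(qalys, dtype=float)
    pts = list(range(len(costs)))
    cur = min(pts, key=lambda i: (costs[i], -qalys[i]))
    frontier = {cur}
    while True:
        cands = [i for i in pts if qalys[i] > qalys[cur]]
        if not cands:
            break
        with np.errstate(over="ignore", divide="ignore"):
            cur = min(
                cands,
                key=lambda i: ((costs[i] - costs[cur]) / (qalys[i] - qalys[cur]), -qalys[i]),
            )
        frontier.add(cur)
    return frontier
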