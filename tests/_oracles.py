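"""Independent oracles used by the scissors tests: brute-force shortest paths.

Kept deliberately separate from the package: the DFS enumerates (with
cost-bound pruning) every simple 8-connected path, so it shares nothing
with the Dijkstra implementation it checks.
"""

from __future__ import annotations

import numpy as np

from renasl.scissors import OFFSETS, CostMap


def random_cost_map(shape: tuple[int, int], rng: np.random.Generator) -> CostMap:
    """Random positive link costs on an 8-connected grid (inf off-image)."""
    rows, cols = shape
    costs = rng.uniform(0.01, 1.0, size=(len(OFFSETS), rows, cols))
    for k, (dr, dc) in enumerate(OFFSETS):
        if dr == -1:
            costs[k, 0, :] = np.inf
        if dr == 1:
            costs[k, -1, :] = np.inf
        if dc == -1:
            costs[k, :, 0] = np.inf
        if dc == 1:
            costs[k, :, -1] = np.inf
    return CostMap(link_costs=costs, weights=(0.43, 0.43, 0.14))


def brute_force_min_cost(
    cost_map: CostMap, seed: tuple[int, int], target: tuple[int, int]
) -> float:
    """Minimum path cost by exhaustive DFS over simple paths, with pruning."""
    rows, cols = cost_map.shape
    lc = cost_map.link_costs
    best = [np.inf]
    visited = np.zeros((rows, cols), dtype=bool)

    def dfs(r: int, c: int, cost: float) -> None:
        if cost >= best[0]:
            return
        if (r, c) == target:
            best[0] = cost
            return
        visited[r, c] = True
        for k, (dr, dc) in enumerate(OFFSETS):
            w = lc[k, r, c]
            if not np.isfinite(w):
                continue
            nr, nc = r + dr, c + dc
            if not visited[nr, nc]:
                dfs(nr, nc, cost + w)
        visited[r, c] = False

    dfs(seed[0], seed[1], 0.0)
    return best[0]
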