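"""Targeted-attack resilience of thresholded covariance networks.

Nodes are deleted one by one in descending order of normalized betweenness
centrality (ties: higher degree first, then region id), and after each
deletion the size of the largest connected component (LCC) is recomputed.
The robustness of a network is the trapezoid area under the curve of
relative LCC size (LCC / original N) versus the fraction of nodes removed —
a number in [0, 1] comparable across parcellation sizes.

The removal order is computed once on the intact graph (static attack, the
default); a variant recomputing centrality after every removal is available.
The LCC sequence for a static order is obtained in reverse with a union-find
pass (adding nodes back), which is linear in edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .graphs import (NodeMetrics, betweenness, curve_auc, make_curve,
                     threshold_at_sparsity, PropertyCurve)
from .io import BinaryGraph


@dataclass(frozen=True)
class AttackCurve:
    """Relative largest-component size after 0..N targeted removals."""

    removed: np.ndarray            # 0, 1, ..., N
    relative_lcc: np.ndarray       # LCC size / original N, non-increasing
    robustness_auc: float          # trapezoid area vs fraction removed
    removal_order: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"removed": self.removed.tolist(),
                "relative_lcc": self.relative_lcc.tolist(),
                "robustness_auc": self.robustness_auc,
                "removal_order": list(self.removal_order)}


def _removal_order(graph: BinaryGraph, metrics: NodeMetrics) -> list[int]:
    ids = graph.region_ids or tuple(str(i) for i in range(graph.n_nodes))
    keys = [(-metrics.nbc[i], -int(metrics.degree[i]), ids[i], i)
            for i in range(graph.n_nodes)]
    keys.sort()
    return [k[-1] for k in keys]


def _lcc_sequence(adjacency: np.ndarray, order: list[int]) -> np.ndarray:
    """LCC size after removing order[:k], for k = 0..N (reverse union-find)."""
    n = adjacency.shape[0]
    parent = np.arange(n)
    size = np.ones(n, dtype=int)
    present = np.zeros(n, dtype=bool)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    lcc_after = np.zeros(n + 1, dtype=int)
    best = 0
    for k in range(n - 1, -1, -1):
        node = order[k]
        present[node] = True
        best = max(best, 1)
        for nb in np.nonzero(adjacency[node])[0]:
            if not present[nb]:
                continue
            ra, rb = find(node), find(nb)
            if ra != rb:
                if size[ra] < size[rb]:
                    ra, rb = rb, ra
                parent[rb] = ra
                size[ra] += size[rb]
                best = max(best, size[ra])
        lcc_after[k] = best
    lcc_after[n] = 0
    return lcc_after


def targeted_attack(graph: BinaryGraph, metrics: NodeMetrics | None = None,
                    recompute: bool = False) -> AttackCurve:
    """Attack curve and robustness AUC for one binary graph.

    ``metrics`` may carry precomputed betweenness for the intact graph; it is
    ignored when ``recompute`` is true (centrality re-evaluated on the
    shrinking graph after every removal).
    """
    n = graph.n_nodes
    if n < 2:
        raise DegenerateDataError("targeted attack needs at least 2 nodes")
    ids = graph.region_ids or tuple(str(i) for i in range(n))
    if recompute:
        order = _recomputed_order(graph)
    else:
        if metrics is None:
            metrics = betweenness(graph)
        order = _removal_order(graph, metrics)
    lcc = _lcc_sequence(graph.adjacency, order)
    relative = lcc / float(n)
    removed = np.arange(n + 1)
    auc = curve_auc(removed / float(n), relative)
    return AttackCurve(removed=removed, relative_lcc=relative,
                       robustness_auc=auc,
                       removal_order=tuple(ids[i] for i in order))


def _recomputed_order(graph: BinaryGraph) -> list[int]:
    ids = graph.region_ids or tuple(str(i) for i in range(graph.n_nodes))
    adj = graph.adjacency.copy()
    alive = list(range(graph.n_nodes))
    order: list[int] = []
    while alive:
        sub = adj[np.ix_(alive, alive)]
        sub_graph = BinaryGraph(adjacency=sub, sparsity=graph.sparsity,
                                threshold=graph.threshold,
                                region_ids=tuple(ids[i] for i in alive))
        metrics = betweenness(sub_graph)
        local = _removal_order(sub_graph, metrics)[0]
        order.append(alive.pop(local))
    return order


def robustness_over_grid(corr: pd.DataFrame, grid: np.ndarray,
                         recompute: bool = False) -> PropertyCurve:
    """Robustness AUC at every sparsity, as a property curve with its own AUC."""
    grid = np.asarray(grid, dtype=float)
    values = []
    for s in grid:
        graph = threshold_at_sparsity(corr, float(s))
        values.append(targeted_attack(graph, recompute=recompute).robustness_auc)
    return make_curve("robustness", grid, np.array(values))
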