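"""Binary graphs from sparsity thresholding and their topological metrics.

A correlation matrix is binarized over a grid of sparsity degrees s (default
0.50 to 0.90 in steps of 0.02, 21 points): at sparsity s the weakest fraction
s of |C_ij| magnitudes is discarded and an edge is kept iff |C_ij| > R_k,
where R_k is the corresponding magnitude cutoff.  Every thresholded graph
therefore has the same number of nodes and (up to ties) edges, making
topological attributes comparable across groups.

Metrics on a graph G = [N, K]:

* clustering index  C_i = existing links among the neighbors of i over all
  their possible links; C = mean over all N nodes (C = 1 iff G is complete);
* characteristic path length L = mean geodesic distance d_ij; infinite
  distances (disconnected pairs) are excluded from the mean and their
  fraction reported alongside;
* global efficiency E_glob = mean of 1/d_ij with 1/inf = 0;
* local efficiency E_loc = mean over nodes of E_glob of the subgraph induced
  by each node's neighbors (0 for degree < 2);
* betweenness B_i = number of shortest paths running through i, counted
  fractionally over equal-length alternatives (Freeman/Brandes definition),
  endpoints excluded; normalized betweenness b_i = B_i / <B> with <B> the
  mean over all N nodes.  Nodes with b_i > 1.5 are hubs.

Everything is vectorized: distances by boolean-matrix BFS, shortest-path
counts by the walk-count identity (walks of length d(s,t) are exactly the
geodesics), betweenness by the path-count decomposition
sigma_si * sigma_it / sigma_st on the distance criterion
d(s,i) + d(i,t) = d(s,t).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, InvariantError
from .io import BinaryGraph, validate_correlation_matrix

GRAPH_PROPERTIES = ("clustering", "path_length", "global_efficiency",
                    "local_efficiency")


# ---------------------------------------------------------------------------
# sparsity grid and thresholding
# ---------------------------------------------------------------------------

def sparsity_grid(lo: float = 0.50, hi: float = 0.90,
                  step: float = 0.02) -> np.ndarray:
    """Ordered sparsity values; defaults give the canonical 21-point grid."""
    if not (0 <= lo <= hi < 1) or step <= 0:
        raise InvariantError("need 0 <= lo <= hi < 1 and step > 0")
    n = int(round((hi - lo) / step)) + 1
    grid = lo + step * np.arange(n)
    grid = np.round(grid, 10)
    if len(grid) > 1 and not (np.diff(grid) > 0).all():
        raise InvariantError("sparsity grid must be strictly increasing")
    return grid


def threshold_at_sparsity(corr: pd.DataFrame, sparsity: float) -> BinaryGraph:
    """Binarize |C_ij| keeping the top (1 - sparsity) fraction of magnitudes.

    R_k is the empirical sparsity-quantile of the N(N-1)/2 off-diagonal
    magnitudes; edges satisfy the strict rule |C_ij| > R_k.  With distinct
    magnitudes the edge count is exactly round((1-s) * N(N-1)/2); ties at R_k
    can only undershoot the target (logged as a warning).
    """
    validate_correlation_matrix(corr)
    if not 0.0 <= sparsity < 1.0:
        raise InvariantError("sparsity must lie in [0, 1)")
    values = corr.to_numpy(dtype=float)
    n = values.shape[0]
    if n < 2:
        raise DegenerateDataError("need at least 2 regions to build a graph")
    iu = np.triu_indices(n, k=1)
    mags = np.abs(values[iu])
    if mags.max() == mags.min():
        raise DegenerateDataError(
            "all |C_ij| identical: target sparsity unachievable (tie-degenerate)")
    k_pairs = len(mags)
    m_target = int(round((1.0 - sparsity) * k_pairs))
    if m_target >= k_pairs:
        rk = 0.0
    elif m_target <= 0:
        rk = float(mags.max())
    else:
        rk = float(np.sort(mags)[k_pairs - m_target - 1])
    # threshold the upper triangle and mirror: 1-ulp asymmetries in the input
    # must not produce an asymmetric adjacency under the strict comparison
    upper = np.triu(np.abs(values), k=1) > rk
    adjacency = upper | upper.T
    graph = BinaryGraph(adjacency=adjacency, sparsity=float(sparsity),
                        threshold=rk,
                        region_ids=tuple(str(c) for c in corr.columns))
    if graph.n_edges != m_target:
        warnings.warn(
            f"tied |C_ij| at R_k={rk:.6g}: realized {graph.n_edges} edges "
            f"vs target {m_target}", UserWarning, stacklevel=2)
    return graph


# ---------------------------------------------------------------------------
# distances and path counts (vectorized BFS)
# ---------------------------------------------------------------------------

def pairwise_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs geodesic lengths of an unweighted graph (inf if unreachable)."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    if n == 0 or not adj.any():
        return dist
    dist[adj] = 1.0
    a = adj.astype(np.float64)
    reach = adj | np.eye(n, dtype=bool)
    d = 1
    while True:
        new_reach = (reach.astype(np.float64) @ a) > 0
        new_reach |= reach
        newly = new_reach & ~reach
        if not newly.any():
            return dist
        d += 1
        dist[newly] = d
        reach = new_reach


def shortest_path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t]: the number of geodesics between s and t (1 on the diagonal).

    Uses the identity that a walk of length d(s, t) cannot revisit a node, so
    the (s, t) entry of A^d(s,t) counts exactly the shortest paths.
    """
    a = np.asarray(adj, dtype=np.float64)
    n = a.shape[0]
    sigma = np.zeros((n, n))
    finite = np.isfinite(dist)
    dmax = int(dist[finite].max()) if finite.any() else 0
    power = a.copy()
    for d in range(1, dmax + 1):
        sel = dist == d
        sigma[sel] = power[sel]
        if d < dmax:
            power = power @ a
    np.fill_diagonal(sigma, 1.0)
    return sigma


def _efficiency_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(dist) & off, 1.0 / np.where(dist > 0, dist, 1.0), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathLengthResult:
    """Characteristic path length over connected pairs, plus the excluded part."""

    value: float
    disconnected_pair_fraction: float

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node attributes of one binary graph."""

    clustering: np.ndarray       # C_i in [0, 1]
    betweenness: np.ndarray      # B_i, fractional counts over unordered pairs
    nbc: np.ndarray              # b_i = B_i / <B>; all 0 with flag if <B> = 0
    degree: np.ndarray
    mean_betweenness: float
    nbc_defined: bool
    region_ids: tuple[str, ...] = field(default=())


def clustering(graph: BinaryGraph) -> tuple[np.ndarray, float]:
    """Per-node clustering indices C_i and their mean C over all N nodes."""
    a = graph.adjacency.astype(np.float64)
    deg = a.sum(axis=1)
    triangles2 = ((a @ a) * a).sum(axis=1)  # = 2 * triangles through each node
    possible = deg * (deg - 1.0)
    ci = np.where(possible > 0, triangles2 / np.where(possible > 0, possible, 1.0), 0.0)
    return ci, float(ci.mean()) if len(ci) else float("nan")


def path_length(graph: BinaryGraph) -> PathLengthResult:
    """Mean geodesic length over connected ordered pairs (NaN if none)."""
    dist = pairwise_distances(graph.adjacency)
    n = graph.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    n_off = n * (n - 1)
    if n_off == 0 or not finite.any():
        return PathLengthResult(float("nan"), 1.0 if n_off else 0.0)
    return PathLengthResult(float(dist[finite].mean()),
                            float(1.0 - finite.sum() / n_off))


def global_efficiency(graph: BinaryGraph) -> float:
    """Mean of 1/d_ij over all ordered pairs (1/inf = 0); 0 for empty graphs."""
    return _efficiency_from_distances(pairwise_distances(graph.adjacency))


def local_efficiency(graph: BinaryGraph) -> float:
    """Mean over nodes of the neighbor-subgraph global efficiency."""
    return float(local_efficiency_per_node(graph).mean()) if graph.n_nodes else float("nan")


def local_efficiency_per_node(graph: BinaryGraph) -> np.ndarray:
    adj = graph.adjacency
    n = graph.n_nodes
    out = np.zeros(n)
    deg = adj.sum(axis=1)
    for i in np.nonzero(deg >= 2)[0]:
        nb = adj[i]
        sub = adj[np.ix_(nb, nb)]
        out[i] = _efficiency_from_distances(pairwise_distances(sub))
    return out


def betweenness_values(adj: np.ndarray, dist: np.ndarray | None = None,
                       sigma: np.ndarray | None = None) -> np.ndarray:
    """Fractional betweenness B_i over unordered pairs, endpoints excluded."""
    adj = np.asarray(adj, dtype=bool)
    n = adj.shape[0]
    if dist is None:
        dist = pairwise_distances(adj)
    if sigma is None:
        sigma = shortest_path_counts(adj, dist)
    finite = np.isfinite(dist)
    denom = np.where((sigma > 0) & finite, sigma, 1.0)
    b = np.zeros(n)
    for i in range(n):
        on_path = finite & (dist[:, [i]] + dist[[i], :] == dist)
        on_path[i, :] = False
        on_path[:, i] = False
        np.fill_diagonal(on_path, False)
        contrib = np.where(on_path, np.outer(sigma[:, i], sigma[i, :]) / denom, 0.0)
        b[i] = contrib.sum() / 2.0
    return b


def betweenness(graph: BinaryGraph) -> NodeMetrics:
    """Full per-node metrics: C_i, B_i, b_i = B_i/<B>, degree."""
    adj = graph.adjacency
    b = betweenness_values(adj)
    mean_b = float(b.mean()) if len(b) else 0.0
    defined = mean_b > 0
    nbc = b / mean_b if defined else np.zeros_like(b)
    ci, _ = clustering(graph)
    return NodeMetrics(
        clustering=ci, betweenness=b, nbc=nbc,
        degree=adj.sum(axis=1).astype(int),
        mean_betweenness=mean_b, nbc_defined=defined,
        region_ids=graph.region_ids)


def identify_hubs(metrics: NodeMetrics, threshold: float = 1.5
                  ) -> list[tuple[str, float]]:
    """Regions with b_i strictly above the hub threshold, sorted by b_i desc."""
    ids = metrics.region_ids or tuple(str(i) for i in range(len(metrics.nbc)))
    hubs = [(ids[i], float(metrics.nbc[i]))
            for i in range(len(metrics.nbc)) if metrics.nbc[i] > threshold]
    hubs.sort(key=lambda item: (-item[1], item[0]))
    return hubs


# ---------------------------------------------------------------------------
# property curves over the sparsity grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyCurve:
    """A network attribute sampled over the sparsity grid, with its AUC."""

    name: str
    sparsities: np.ndarray
    values: np.ndarray
    auc: float

    def __post_init__(self):
        if len(self.sparsities) != len(self.values):
            raise InvariantError("sparsities and values must have equal length")

    def to_dict(self) -> dict:
        return {"name": self.name, "sparsities": self.sparsities.tolist(),
                "values": self.values.tolist(), "auc": self.auc}


def curve_auc(sparsities: np.ndarray, values: np.ndarray) -> float:
    """Trapezoid area under a property curve along the sparsity axis."""
    if len(sparsities) < 2:
        warnings.warn("single-point grid: AUC defined as 0", UserWarning,
                      stacklevel=2)
        return 0.0
    return float(np.trapezoid(values, sparsities))


def make_curve(name: str, sparsities: np.ndarray, values: np.ndarray) -> PropertyCurve:
    sparsities = np.asarray(sparsities, dtype=float)
    values = np.asarray(values, dtype=float)
    return PropertyCurve(name, sparsities, values, curve_auc(sparsities, values))


def graph_metrics(graph: BinaryGraph) -> dict[str, float]:
    """The four global attributes of one graph, sharing one distance pass."""
    dist = pairwise_distances(graph.adjacency)
    n = graph.n_nodes
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    _, c = clustering(graph)
    lvalue = float(dist[finite].mean()) if finite.any() else float("nan")
    return {
        "clustering": c,
        "path_length": lvalue,
        "global_efficiency": _efficiency_from_distances(dist),
        "local_efficiency": local_efficiency(graph),
    }


def property_curves(corr: pd.DataFrame, grid: np.ndarray
                    ) -> dict[str, PropertyCurve]:
    """One curve (and AUC) per global attribute over the sparsity grid."""
    grid = np.asarray(grid, dtype=float)
    rows = {name: [] for name in GRAPH_PROPERTIES}
    for s in grid:
        metrics = graph_metrics(threshold_at_sparsity(corr, float(s)))
        for name in GRAPH_PROPERTIES:
            rows[name].append(metrics[name])
    return {name: make_curve(name, grid, np.array(vals))
            for name, vals in rows.items()}
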