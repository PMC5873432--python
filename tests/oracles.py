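"""Independent brute-force oracles for graph metrics (tiny graphs only).

Everything here is deliberately naive — triple loops, explicit path
enumeration — so it shares no code path with the package's vectorized
implementations.
"""

from __future__ import annotations

import numpy as np


def random_adjacency(n: int, p: float, rng: np.random.Generator) -> np.ndarray:
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, k=1)
    return adj | adj.T


def fw_distances(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall all-pairs distances."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for i in range(n):
        dist[i, i] = 0.0
        for j in range(n):
            if adj[i, j]:
                dist[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def brute_clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node triangle/triple counting."""
    n = adj.shape[0]
    ci = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a in range(k) for b in range(a + 1, k)
                    if adj[nbrs[a], nbrs[b]])
        ci[i] = links / (k * (k - 1) / 2)
    return ci, float(ci.mean())


def brute_path_length(adj: np.ndarray) -> float:
    dist = fw_distances(adj)
    vals = [dist[i, j] for i in range(len(adj)) for j in range(len(adj))
            if i != j and np.isfinite(dist[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def brute_global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n < 2:
        return 0.0
    dist = fw_distances(adj)
    total = sum(1.0 / dist[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(dist[i, j]))
    return total / (n * (n - 1))


def brute_local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    effs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        effs.append(brute_global_efficiency(sub))
    return float(np.mean(effs)) if effs else float("nan")


def enumerate_shortest_paths(adj: np.ndarray, s: int, t: int,
                             dist: np.ndarray) -> list[list[int]]:
    """All geodesics from s to t by DFS along decreasing distance-to-t."""
    if not np.isfinite(dist[s, t]):
        return []
    if s == t:
        return [[s]]
    paths = []
    for u in range(len(adj)):
        if adj[s, u] and dist[u, t] == dist[s, t] - 1:
            for tail in enumerate_shortest_paths(adj, u, t, dist):
                paths.append([s] + tail)
    return paths


def brute_betweenness(adj: np.ndarray) -> np.ndarray:
    """Fractional betweenness by explicit enumeration of every geodesic."""
    n = adj.shape[0]
    dist = fw_distances(adj)
    b = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_shortest_paths(adj, s, t, dist)
            if not paths:
                continue
            for path in paths:
                for node in path[1:-1]:
                    b[node] += 1.0 / len(paths)
    return b
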