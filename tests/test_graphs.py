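"""Thresholding rules and graph metrics vs brute-force/networkx oracles."""

import numpy as np
import networkx as nx
import pytest

from covnet import (DegenerateDataError, betweenness, clustering,
                    global_efficiency, identify_hubs, local_efficiency,
                    path_length, property_curves, sparsity_grid,
                    threshold_at_sparsity)
from covnet.graphs import curve_auc, make_curve

import oracles
from conftest import complete_graph, make_graph, random_corr_frame


# ---------------------------------------------------------------------------
# sparsity grid + thresholding
# ---------------------------------------------------------------------------

def test_default_grid_has_21_points():
    grid = sparsity_grid()
    assert len(grid) == 21
    assert grid[0] == 0.50 and grid[-1] == 0.90
    np.testing.assert_allclose(np.diff(grid), 0.02)


def test_threshold_keeps_largest_magnitudes(rng):
    frame = random_corr_frame(5, rng)
    graph = threshold_at_sparsity(frame, 0.8)
    assert graph.n_edges == 2
    vals = np.abs(frame.to_numpy()[np.triu_indices(5, k=1)])
    kept = np.abs(frame.to_numpy())[graph.adjacency]
    assert kept.min() > np.sort(vals)[-3]


def test_sparsity_09_keeps_ten_percent_of_114_regions(rng):
    frame = random_corr_frame(114, rng)
    graph = threshold_at_sparsity(frame, 0.9)
    assert graph.n_edges == round(0.1 * 114 * 113 / 2) == 644


def test_negative_correlation_with_largest_magnitude_retained(rng):
    frame = random_corr_frame(6, rng)
    vals = frame.to_numpy() * 0.5
    vals[0, 1] = vals[1, 0] = -0.95
    np.fill_diagonal(vals, 0.0)
    frame.iloc[:, :] = vals
    graph = threshold_at_sparsity(frame, 0.9)
    assert graph.adjacency[0, 1]


def test_all_tied_magnitudes_degenerate(rng):
    import pandas as pd
    vals = np.full((4, 4), 0.5)
    np.fill_diagonal(vals, 0.0)
    frame = pd.DataFrame(vals, index=list("abcd"), columns=list("abcd"))
    with pytest.raises(DegenerateDataError, match="tie"):
        threshold_at_sparsity(frame, 0.5)


def test_nested_thresholding(rng):
    frame = random_corr_frame(30, rng)
    grid = sparsity_grid()
    prev = None
    for s in grid:
        adj = threshold_at_sparsity(frame, float(s)).adjacency
        if prev is not None:
            assert not (adj & ~prev).any()  # edge sets shrink with sparsity
        prev = adj


# ---------------------------------------------------------------------------
# single-graph metrics on hand-enumerable cases
# ---------------------------------------------------------------------------

def test_complete_graph_boundary_values():
    k5 = complete_graph(5)
    _, c = clustering(k5)
    assert c == 1.0
    assert float(path_length(complete_graph(4))) == 1.0
    assert global_efficiency(k5) == pytest.approx(1.0)
    assert local_efficiency(complete_graph(4)) == pytest.approx(1.0)
    metrics = betweenness(k5)
    assert np.all(metrics.betweenness == 0.0)
    assert not metrics.nbc_defined and np.all(metrics.nbc == 0.0)


def test_path_graph_enumeration(path_graph):
    ci, c = clustering(path_graph)
    assert c == 0.0 and ci[1] == 0.0
    assert float(path_length(path_graph)) == pytest.approx(4 / 3)
    metrics = betweenness(path_graph)
    np.testing.assert_allclose(metrics.betweenness, [0.0, 1.0, 0.0])
    assert metrics.mean_betweenness == pytest.approx(1 / 3)
    np.testing.assert_allclose(metrics.nbc, [0.0, 3.0, 0.0])
    assert identify_hubs(metrics) == [("b", 3.0)]


def test_two_disjoint_edges_efficiency_and_path_length():
    adj = np.zeros((4, 4), dtype=bool)
    adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = True
    g = make_graph(adj)
    assert global_efficiency(g) == pytest.approx(1 / 3)
    pl = path_length(g)
    assert float(pl) == 1.0
    assert pl.disconnected_pair_fraction == pytest.approx(8 / 12)


def test_star_graph_local_efficiency_zero():
    adj = np.zeros((6, 6), dtype=bool)
    adj[0, 1:] = adj[1:, 0] = True
    assert local_efficiency(make_graph(adj)) == 0.0


def test_empty_graph_conventions():
    g = make_graph(np.zeros((4, 4), dtype=bool))
    assert global_efficiency(g) == 0.0
    assert np.isnan(float(path_length(g)))
    _, c = clustering(g)
    assert c == 0.0


def test_hub_rule_strict_inequality():
    from covnet.graphs import NodeMetrics
    metrics = NodeMetrics(clustering=np.zeros(3), betweenness=np.array([3, 1.5, 0.2]),
                          nbc=np.array([3.0, 1.5, 0.2]), degree=np.array([2, 2, 2]),
                          mean_betweenness=1.0, nbc_defined=True,
                          region_ids=("a", "b", "c"))
    assert identify_hubs(metrics) == [("a", 3.0)]
    none = NodeMetrics(clustering=np.zeros(2), betweenness=np.ones(2),
                       nbc=np.ones(2), degree=np.ones(2, dtype=int),
                       mean_betweenness=1.0, nbc_defined=True)
    assert identify_hubs(none) == []


# ---------------------------------------------------------------------------
# oracle equivalence on random graphs
# ---------------------------------------------------------------------------

def test_metrics_match_brute_force_oracles(rng):
    """C, L, Eglob, Eloc and B_i equal exhaustive computations (and networkx)
    on random graphs with up to 10 nodes."""
    for rep in range(60):
        n = int(rng.integers(2, 11))
        adj = oracles.random_adjacency(n, float(rng.uniform(0.15, 0.9)), rng)
        g = make_graph(adj)
        _, c = clustering(g)
        assert c == pytest.approx(oracles.brute_clustering(adj)[1], abs=1e-9)
        l_pkg = float(path_length(g))
        l_ref = oracles.brute_path_length(adj)
        if np.isnan(l_ref):
            assert np.isnan(l_pkg)
        else:
            assert l_pkg == pytest.approx(l_ref, abs=1e-9)
        assert global_efficiency(g) == pytest.approx(
            oracles.brute_global_efficiency(adj), abs=1e-9)
        assert local_efficiency(g) == pytest.approx(
            oracles.brute_local_efficiency(adj), abs=1e-9)
        b_pkg = betweenness(g).betweenness
        np.testing.assert_allclose(b_pkg, oracles.brute_betweenness(adj),
                                   atol=1e-9)
        # cross-check against an independent library implementation
        gx = nx.from_numpy_array(adj.astype(int))
        b_nx = np.array([v for _, v in sorted(
            nx.betweenness_centrality(gx, normalized=False).items())])
        np.testing.assert_allclose(b_pkg, b_nx, atol=1e-9)
        c_nx = np.mean(list(nx.clustering(gx).values()))
        assert c == pytest.approx(c_nx, abs=1e-9)


def test_mean_nbc_is_one_when_defined(rng):
    for rep in range(20):
        adj = oracles.random_adjacency(8, 0.4, rng)
        metrics = betweenness(make_graph(adj))
        if metrics.nbc_defined:
            assert metrics.nbc.mean() == pytest.approx(1.0, abs=1e-12)
        else:
            assert np.all(metrics.nbc == 0.0)


# ---------------------------------------------------------------------------
# property curves
# ---------------------------------------------------------------------------

def test_constant_curve_auc_rectangle():
    grid = sparsity_grid(0.5, 0.9, 0.02)
    curve = make_curve("c", grid, np.ones(len(grid)))
    assert curve.auc == pytest.approx(0.4, abs=1e-12)


def test_single_point_grid_auc_zero_with_warning():
    with pytest.warns(UserWarning, match="single-point"):
        assert curve_auc(np.array([0.5]), np.array([1.0])) == 0.0


def test_global_efficiency_curve_non_increasing(rng):
    frame = random_corr_frame(25, rng)
    curves = property_curves(frame, sparsity_grid())
    eglob = curves["global_efficiency"].values
    assert np.all(np.diff(eglob) <= 1e-12)
    for name in ("clustering", "global_efficiency", "local_efficiency"):
        vals = curves[name].values
        assert np.all((vals >= 0) & (vals <= 1))
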