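import math

import networkx as nx
import numpy as np
import pytest

import oracles
from conftest import random_graph
from netpharm.centrality import (betweenness_centrality, closeness_centrality,
                                 compute_all, degree_centrality,
                                 edge_clustering_coefficient,
                                 eigenvector_centrality,
                                 local_average_connectivity, network_centrality)


def test_k3_closed_forms(k3):
    table = compute_all(k3)
    for node in "abc":
        row = table.loc[node]
        assert row["dc"] == 2
        assert row["bc"] == 0
        assert row["cc"] == 1.0
        assert row["ec"] == pytest.approx(1 / math.sqrt(3), abs=1e-9)
        assert row["lac"] == 1.0
        assert row["nc"] == 2.0


def test_star_closed_forms(star4):
    table = compute_all(star4)
    center = table.loc["h"]
    assert center["dc"] == 4
    assert center["bc"] == 6  # C(4,2) leaf pairs route through the center
    assert center["lac"] == 0.0  # no edges among leaves
    assert center["nc"] == 0.0  # every ECC denominator vanishes
    leaf = table.loc["l1"]
    assert leaf["bc"] == 0
    assert leaf["cc"] == pytest.approx(4 / 7)


def test_degree_equals_adjacency_row_sums(rg12):
    a = nx.to_numpy_array(rg12, nodelist=sorted(rg12.nodes))
    dc = degree_centrality(rg12)
    for i, n in enumerate(sorted(rg12.nodes)):
        assert dc[n] == a[i].sum()


def test_isolated_node_scores_zero():
    g = nx.Graph()
    g.add_edge("a", "b")
    g.add_node("z")
    table = compute_all(g)
    assert (table.loc["z"] == 0).all()


@pytest.mark.parametrize("seed", range(6))
def test_random_graphs_match_oracles(seed):
    g = random_graph(12, 0.3, seed=seed + 100)
    checks = [
        (betweenness_centrality, oracles.bc_oracle),
        (closeness_centrality, oracles.cc_oracle),
        (eigenvector_centrality, oracles.ec_oracle),
        (local_average_connectivity, oracles.lac_oracle),
        (network_centrality, oracles.nc_oracle),
    ]
    for fast, oracle in checks:
        got, want = fast(g), oracle(g)
        for n in g.nodes:
            assert got[n] == pytest.approx(want[n], abs=1e-8), (fast.__name__, n)


@pytest.mark.parametrize("g", [nx.cycle_graph(7), nx.complete_graph(5)],
                         ids=["cycle7", "K5"])
def test_vertex_transitive_graphs_are_constant(g):
    table = compute_all(g)
    for m in table.columns:
        assert table[m].nunique() == 1, m


def test_ecc_conventions():
    g = nx.complete_graph(3)
    assert edge_clustering_coefficient(g, 0, 1) == 1.0
    assert edge_clustering_coefficient(g, 0, 1, plus_one=True) == 2.0
    star = nx.star_graph(3)
    assert edge_clustering_coefficient(star, 0, 1) == 0.0  # degree-1 endpoint


def test_eigenvector_restricted_to_largest_component():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])  # size 4
    g.add_edges_from([("x", "y")])  # size 2
    ec = eigenvector_centrality(g)
    assert ec["x"] == 0.0 and ec["y"] == 0.0
    vec = np.array([ec[n] for n in "abcd"])
    assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-9)
    ec2 = eigenvector_centrality(g, scope="per-component")
    assert ec2["x"] == pytest.approx(1 / math.sqrt(2), abs=1e-9)


def test_eigenvector_convergence_error():
    from netpharm.centrality import ConvergenceError
    with pytest.raises(ConvergenceError, match="residual"):
        eigenvector_centrality(nx.path_graph(30), tol=1e-15, max_iter=2)


def test_adding_edge_never_decreases_endpoint_degree(rg12):
    dc = degree_centrality(rg12)
    nodes = sorted(rg12.nodes)
    for u, v in [(nodes[0], nodes[5]), (nodes[2], nodes[9])]:
        if rg12.has_edge(u, v):
            continue
        h = rg12.copy()
        h.add_edge(u, v)
        dc2 = degree_centrality(h)
        assert dc2[u] >= dc[u] and dc2[v] >= dc[v]


def test_compute_all_contract(rg12):
    with pytest.raises(ValueError, match="unknown"):
        compute_all(rg12, ("dc", "bogus"))
    assert compute_all(nx.Graph()).empty
    table = compute_all(rg12, ("dc", "bc", "cc", "ec", "lac", "nc", "sc", "ic"))
    assert list(table.columns) == ["dc", "bc", "cc", "ec", "lac", "nc", "sc", "ic"]
    assert not table.isna().any().any()


def test_table_round_trip(tmp_path, rg12):
    import pandas as pd
    table = compute_all(rg12)
    p = tmp_path / "cent.tsv"
    table.to_csv(p, sep="\t")
    back = pd.read_csv(p, sep="\t", index_col="node")
    pd.testing.assert_frame_equal(table, back)
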