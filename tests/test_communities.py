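"""Louvain partitions, modularity, layer-preserving randomization and
null-ensemble statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest

from phytonet.communities import (NullEnsemble, convergence_trajectory,
                                  empirical_p, louvain_partition, modularity,
                                  null_test, randomize)
from conftest import make_table
from phytonet.network import assert_tripartite, build_network


def two_triangles():
    G = nx.Graph()
    G.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
    return G


# -------------------------------------------------------------------- louvain

def test_two_triangles_found_with_q_half():
    part = louvain_partition(two_triangles(), seed=0)
    comms = part.communities()
    assert len(comms) == 2
    assert set(map(frozenset, comms.values())) == {frozenset({0, 1, 2}),
                                                   frozenset({3, 4, 5})}
    assert part.modularity_q == pytest.approx(0.5)


def test_single_edge_one_community_q_zero():
    G = nx.Graph([(0, 1)])
    part = louvain_partition(G, seed=0)
    assert len(set(part.assignment.values())) == 1
    assert part.modularity_q == pytest.approx(0.0)


def test_louvain_deterministic_given_seed(default_network):
    a = louvain_partition(default_network, seed=42).assignment
    b = louvain_partition(default_network, seed=42).assignment
    assert a == b


def test_edgeless_graph_gets_singletons():
    G = nx.empty_graph(4)
    part = louvain_partition(G, seed=0)
    assert len(set(part.assignment.values())) == 4
    assert part.modularity_q == 0.0


def test_louvain_beats_singleton_partition(default_network):
    part = louvain_partition(default_network, seed=1)
    singletons = {n: i for i, n in enumerate(default_network.nodes())}
    assert part.modularity_q >= modularity(default_network, singletons)


# ----------------------------------------------------------------- modularity

def _modularity_double_sum(G, assignment):
    """Independent oracle: (1/2m) sum_ij (A_ij - d_i d_j / 2m) delta(ci, cj)."""
    m = G.number_of_edges()
    deg = dict(G.degree())
    nodes = list(G.nodes())
    q = 0.0
    for i in nodes:
        for j in nodes:
            if assignment[i] != assignment[j]:
                continue
            a = 1.0 if G.has_edge(i, j) else 0.0
            q += a - deg[i] * deg[j] / (2.0 * m)
    return q / (2.0 * m)


def test_modularity_hand_values():
    G = two_triangles()
    true_split = {0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}
    assert modularity(G, true_split) == pytest.approx(0.5)
    one = {n: 0 for n in G.nodes()}
    assert modularity(G, one) == pytest.approx(0.0)


def test_modularity_matches_double_sum_oracle():
    rng = np.random.default_rng(5)
    for _ in range(25):
        n = int(rng.integers(3, 9))
        G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 20)))
        if G.number_of_edges() == 0:
            continue
        assignment = {v: int(rng.integers(3)) for v in G.nodes()}
        assert modularity(G, assignment) == pytest.approx(
            _modularity_double_sum(G, assignment), abs=1e-12)


def test_modularity_errors():
    with pytest.raises(ValueError):
        modularity(nx.empty_graph(3), {0: 0, 1: 0, 2: 0})
    with pytest.raises(ValueError):
        modularity(nx.Graph([(0, 1)]), {0: 0})


# -------------------------------------------------------------- randomization

def _degree_by_node(G):
    return dict(G.degree())


def test_replicates_preserve_degrees_and_types(default_network):
    orig = _degree_by_node(default_network)
    types = nx.get_node_attributes(default_network, "entity_type")
    for H in randomize(default_network, n_iter=5, seed=0):
        assert _degree_by_node(H) == orig
        assert nx.get_node_attributes(H, "entity_type") == types
        assert_tripartite(H)      # still simple & correctly layered


def test_two_disjoint_edges_swap_outcomes():
    G = build_network(make_table([("G1", "C1", None), ("G2", "C2", None)]))
    seen = set()
    for H in randomize(G, n_iter=50, seed=1):
        seen.add(frozenset(frozenset(e) for e in H.edges()))
    allowed = {
        frozenset({frozenset({"G1", "C1"}), frozenset({"G2", "C2"})}),
        frozenset({frozenset({"G1", "C2"}), frozenset({"G2", "C1"})}),
    }
    assert seen <= allowed
    assert len(seen) == 2        # both labeled graphs are reachable


def test_randomize_deterministic_given_seed(default_network):
    a = [frozenset(map(frozenset, H.edges()))
         for H in randomize(default_network, 3, seed=9)]
    b = [frozenset(map(frozenset, H.edges()))
         for H in randomize(default_network, 3, seed=9)]
    assert a == b


def test_single_edge_layer_left_unchanged():
    G = build_network(make_table([("G1", "C1", "P1"), ("G2", "C1", None),
                                  ("G3", "C1", None)]))
    # compound-plant layer has one edge -> must survive every replicate
    for H in randomize(G, 10, seed=2):
        assert H.has_edge("C1", "P1")


# ------------------------------------------------------------ null statistics

def test_empirical_p_extremes():
    samples = np.arange(1000, dtype=float)
    assert empirical_p(samples, 2000.0) == pytest.approx(1 / 1001)
    assert empirical_p(samples, -5.0) == pytest.approx(1.0)


def test_empirical_p_bounds_random():
    rng = np.random.default_rng(0)
    s = rng.standard_normal(57)
    for obs in rng.standard_normal(20):
        p = empirical_p(s, float(obs))
        assert 1 / 58 <= p <= 1.0


def test_convergence_trajectory_definition():
    samples = list(np.linspace(1.0, 2.0, 400))
    traj = dict(convergence_trajectory(samples))
    assert set(traj) == {100, 200, 300, 400}
    cmean = np.cumsum(samples) / np.arange(1, 401)
    # checkpoint 400: window (200, 400] -> cumulative means at 300 and 400
    expect = np.std([cmean[299], cmean[399]]) / abs(cmean[399])
    assert traj[400] == pytest.approx(expect)
    assert all(cv >= 0 for cv in traj.values())


def test_null_test_requires_ten_iterations(default_network):
    with pytest.raises(ValueError):
        null_test(default_network, "modularity", n_iter=5)


def test_null_test_deterministic_and_bounded(default_network):
    a = null_test(default_network, "modularity", n_iter=20, seed=3)
    b = null_test(default_network, "modularity", n_iter=20, seed=3)
    assert a.samples == b.samples
    assert a.observed == b.observed
    assert 1 / 21 <= a.empirical_p <= 1.0


def test_null_test_clustering_and_path_metrics(default_network):
    ens = null_test(default_network, "avg_clustering", n_iter=10, seed=4)
    assert ens.observed == 0.0            # layered graph: no triangles
    ens2 = null_test(default_network, "avg_path_length", n_iter=10, seed=4)
    assert ens2.observed > 1.0


def test_unknown_metric_rejected(default_network):
    with pytest.raises(ValueError):
        null_test(default_network, "diameter", n_iter=10)
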