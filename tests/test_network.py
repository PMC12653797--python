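"""Tripartite construction, density, centralities and topology summary."""

import itertools

import networkx as nx
import numpy as np
import pytest

from phytonet.network import (TripartiteInvariantError, assert_tripartite,
                              build_network, centralities, density,
                              powerlaw_fit_r2, topology_summary)
from phytonet.io_validation import EmptyTableError
from conftest import make_table, random_tripartite_graph


# ---------------------------------------------------------------------- build

def test_build_two_rows_shared_compound():
    G = build_network(make_table([("G1", "C1", "P1"), ("G2", "C1", "P1")]))
    assert G.number_of_nodes() == 4
    assert sorted(map(sorted, G.edges())) == [["C1", "G1"], ["C1", "G2"],
                                              ["C1", "P1"]]


def test_orphan_gene_is_isolated_node():
    G = build_network(make_table([("G1", "C1", "P1"), ("G3", None, None)]))
    assert "G3" in G
    assert G.degree("G3") == 0
    assert G.nodes["G3"]["entity_type"] == "gene"


def test_repeated_pair_weight_frequency():
    rows = [("G1", "C1", f"P{i}") for i in range(5)]
    G = build_network(make_table(rows), weight_by_frequency=True)
    assert G["G1"]["C1"]["weight"] == 5
    G1 = build_network(make_table(rows))
    assert G1["G1"]["C1"]["weight"] == 1


def test_empty_table_errors():
    with pytest.raises(EmptyTableError):
        build_network(make_table([]))


def test_invariants_hold_on_random_builds():
    rng = np.random.default_rng(0)
    for _ in range(20):
        G = random_tripartite_graph(rng)
        assert_tripartite(G)      # raises on violation


def test_assert_tripartite_rejects_gene_plant_edge():
    G = nx.Graph()
    G.add_node("G1", entity_type="gene")
    G.add_node("P1", entity_type="plant")
    G.add_edge("G1", "P1", layer="gene-compound")
    with pytest.raises(TripartiteInvariantError):
        assert_tripartite(G)


# -------------------------------------------------------------------- density

def test_density_examples():
    assert density(nx.complete_graph(4)) == pytest.approx(1.0)
    G = nx.empty_graph(10)
    assert density(G) == 0.0
    with pytest.raises(ValueError):
        density(nx.empty_graph(1))


def test_density_matches_pair_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(15):
        n = int(rng.integers(2, 31))
        G = nx.gnp_random_graph(n, float(rng.random()), seed=int(rng.integers(1 << 20)))
        pairs = sum(1 for u, v in itertools.combinations(G.nodes(), 2)
                    if G.has_edge(u, v))
        assert density(G) == pytest.approx(pairs / (n * (n - 1) / 2))


# --------------------------------------------------------------- centralities

def test_star_center_betweenness_is_pair_count():
    G = build_network(make_table([(f"G{i}", "C1", None) for i in range(4)]))
    prof = centralities(G)
    assert prof.loc["C1", "betweenness"] == pytest.approx(6.0)   # C(4,2)
    assert all(prof.loc[f"G{i}", "betweenness"] == 0 for i in range(4))


def test_path_closeness_convention():
    G = build_network(make_table([("A", "B", None), ("C", "B", None)]))
    prof = centralities(G)
    assert prof.loc["B", "closeness"] == pytest.approx(1.0)
    assert prof.loc["A", "closeness"] == pytest.approx(2 / 3)


def test_isolated_node_conventions():
    G = build_network(make_table([("G1", "C1", None), ("G2", None, None)]))
    prof = centralities(G)
    assert prof.loc["G2", "degree"] == 0
    assert prof.loc["G2", "closeness"] == 0.0
    assert prof.loc["G2", "eigenvector"] == 0.0


def test_degree_centrality_is_degree_over_n_minus_1(default_network):
    prof = centralities(default_network)
    n = default_network.number_of_nodes()
    assert np.allclose(prof["degree_centrality"], prof["degree"] / (n - 1))


def _closeness_oracle(G):
    n = G.number_of_nodes()
    out = {}
    for v in G.nodes():
        d = nx.single_source_shortest_path_length(G, v)
        r = len(d) - 1
        out[v] = 0.0 if r == 0 else (r / sum(d.values())) * (r / (n - 1))
    return out


def _betweenness_oracle(G):
    """Pair-by-pair shortest-path counting, independent of Brandes."""
    out = {v: 0.0 for v in G.nodes()}
    dist, sigma = {}, {}
    for s in G.nodes():
        d = {s: 0}
        sg = {s: 1}
        frontier = [s]
        while frontier:
            nxt = []
            for u in frontier:
                for w in G[u]:
                    if w not in d:
                        d[w] = d[u] + 1
                        sg[w] = 0
                        nxt.append(w)
                    if d[w] == d[u] + 1:
                        sg[w] += sg[u]
            frontier = nxt
        dist[s], sigma[s] = d, sg
    for s, t in itertools.combinations(G.nodes(), 2):
        if t not in dist[s]:
            continue
        dst = dist[s][t]
        for v in G.nodes():
            if v in (s, t) or v not in dist[s] or v not in dist[t]:
                continue
            if dist[s][v] + dist[t][v] == dst:
                out[v] += sigma[s][v] * sigma[t][v] / sigma[s][t]
    return out


def test_betweenness_and_closeness_against_bfs_oracle():
    rng = np.random.default_rng(7)
    for _ in range(5):
        G = random_tripartite_graph(rng, n_genes=10, n_compounds=5,
                                    n_plants=3, p_gc=0.3, p_cp=0.5)
        assert G.number_of_nodes() <= 50
        prof = centralities(G)
        clo = _closeness_oracle(G)
        bet = _betweenness_oracle(G)
        for v in G.nodes():
            assert prof.loc[v, "closeness"] == pytest.approx(clo[v], abs=1e-12)
            assert prof.loc[v, "betweenness"] == pytest.approx(bet[v], abs=1e-9)


# ---------------------------------------------------------------- topo summary

def _typed_graph(n_genes, n_compounds, n_plants):
    rows = []
    compounds = [f"C{i}" for i in range(n_compounds)]
    plants = [f"P{i}" for i in range(n_plants)]
    for i in range(n_genes):
        rows.append((f"G{i}", compounds[i % n_compounds],
                     plants[i % n_plants]))
    return build_network(make_table(rows))


def test_composition_percentages_worked_example():
    G = _typed_graph(108, 32, 3)
    topo = topology_summary(G)
    assert topo.composition == {"gene": 75.5, "compound": 22.4, "plant": 2.1}


def test_composition_sums_to_100():
    rng = np.random.default_rng(3)
    for _ in range(10):
        G = random_tripartite_graph(rng)
        topo = topology_summary(G)
        # 1 d.p. rounding of three percentages drifts at most 0.1 from 100
        assert sum(topo.composition.values()) == pytest.approx(
            100.0, abs=0.1 + 1e-9)


def test_layered_graph_has_zero_clustering(default_network):
    """No triangle can close across gene-compound-plant layers."""
    topo = topology_summary(default_network)
    assert topo.avg_clustering == 0.0


def test_hub_fraction_on_constructed_fixture():
    """3 of 20 compounds reach degree >= 5 -> hub fraction 15%."""
    rows = []
    for ci in range(3):
        for gi in range(5):
            rows.append((f"G{ci}_{gi}", f"HUB{ci}", None))
    for ci in range(17):
        rows.append((f"g{ci}", f"SMALL{ci}", None))
    topo = topology_summary(build_network(make_table(rows)), hub_degree=5)
    assert len(topo.hub_compounds) == 3
    assert topo.hub_compound_fraction == pytest.approx(0.15)


def test_powerlaw_r2_perfect_fit():
    # sizes = rank^-2 exactly -> R^2 = 1
    sizes = [round(1000 * r ** -2) for r in range(1, 6)]
    assert powerlaw_fit_r2(sizes) == pytest.approx(1.0, abs=1e-3)
    assert powerlaw_fit_r2([5]) is None
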