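"""Tripartite network construction and topology metrics.

The network has three node classes (gene, compound, plant) and undirected
edges restricted to adjacent layers: gene-compound and compound-plant.
Gene-plant edges, same-type edges, self-loops and parallel edges are all
forbidden; :func:`assert_tripartite` enforces this on every build.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np
from scipy import stats as sps

from .io_validation import EmptyTableError, RelationshipTable

logger = logging.getLogger("phytonet.network")

NODE_TYPES = ("gene", "compound", "plant")
LAYER_GC = "gene-compound"
LAYER_CP = "compound-plant"
#: valid (sorted type pair) -> layer tag
_LAYERS = {("compound", "gene"): LAYER_GC, ("compound", "plant"): LAYER_CP}


class TripartiteInvariantError(ValueError):
    """An edge or node violates the layered-network invariants."""


def assert_tripartite(G: nx.Graph) -> None:
    """Raise unless every node is typed and every edge joins adjacent layers
    with a matching layer tag."""
    for n, d in G.nodes(data=True):
        if d.get("entity_type") not in NODE_TYPES:
            raise TripartiteInvariantError(f"node {n!r} has invalid type "
                                           f"{d.get('entity_type')!r}")
    for u, v, d in G.edges(data=True):
        if u == v:
            raise TripartiteInvariantError(f"self-loop at {u!r}")
        tu = G.nodes[u]["entity_type"]
        tv = G.nodes[v]["entity_type"]
        layer = _LAYERS.get(tuple(sorted((tu, tv))))
        if layer is None:
            raise TripartiteInvariantError(
                f"edge {u!r}-{v!r} joins layers {tu}/{tv}")
        if d.get("layer") != layer:
            raise TripartiteInvariantError(
                f"edge {u!r}-{v!r} tagged {d.get('layer')!r}, expected {layer!r}")


def build_network(table: RelationshipTable,
                  weight_by_frequency: bool = False) -> nx.Graph:
    """Build the tripartite graph from a cleaned relationship table.

    One node per distinct entity; one edge per distinct co-occurring
    gene-compound or compound-plant pair.  Orphan genes become isolated
    nodes.  Edge weight is 1, or the number of supporting rows when
    ``weight_by_frequency`` is set.
    """
    if not table.rows:
        raise EmptyTableError("cannot build a network from an empty table")
    G = nx.Graph()
    gc: Counter[tuple[str, str]] = Counter()
    cp: Counter[tuple[str, str]] = Counter()
    for r in table.rows:
        G.add_node(r.gene, entity_type="gene")
        if r.compound is not None:
            G.add_node(r.compound, entity_type="compound")
            gc[(r.gene, r.compound)] += 1
        if r.plant is not None:
            G.add_node(r.plant, entity_type="plant")
            if r.compound is not None:
                cp[(r.compound, r.plant)] += 1
    for (g, c), n in gc.items():
        G.add_edge(g, c, layer=LAYER_GC, weight=n if weight_by_frequency else 1)
    for (c, p), n in cp.items():
        G.add_edge(c, p, layer=LAYER_CP, weight=n if weight_by_frequency else 1)
    assert_tripartite(G)
    logger.info("built network: %d nodes, %d edges",
                G.number_of_nodes(), G.number_of_edges())
    return G


def density(G: nx.Graph) -> float:
    """Simple-graph density 2m / (n(n-1)); requires at least two nodes."""
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("density requires at least 2 nodes")
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def centralities(G: nx.Graph, eigen_tol: float = 1e-6,
                 eigen_max_iter: int = 1000):
    """Per-node degree, degree centrality, betweenness, closeness and
    eigenvector centrality as a DataFrame indexed by node.

    Conventions: betweenness is the unnormalized shortest-path pair count;
    closeness uses the Wasserman-Faust scaling by reachable fraction, so
    isolated nodes score 0; eigenvector centrality is computed by power
    iteration on the largest connected component, all other nodes score 0.
    """
    import pandas as pd

    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = list(G.nodes())
    deg = dict(G.degree())
    dc = nx.degree_centrality(G) if len(nodes) > 1 else {nodes[0]: 0.0}
    bet = nx.betweenness_centrality(G, normalized=False)
    clo = nx.closeness_centrality(G, wf_improved=True)
    eig = {n: 0.0 for n in nodes}
    comps = sorted(nx.connected_components(G),
                   key=lambda c: (len(c), min(map(str, c))), reverse=True)
    lcc = comps[0]
    if len(lcc) >= 2:
        try:
            sub = G.subgraph(lcc)
            eig.update(nx.eigenvector_centrality(sub, max_iter=eigen_max_iter,
                                                 tol=eigen_tol))
        except nx.PowerIterationFailedConvergence as exc:
            raise RuntimeError(
                "eigenvector centrality failed to converge on the component "
                f"containing {min(map(str, lcc))!r}") from exc
    return pd.DataFrame({
        "degree": [deg[n] for n in nodes],
        "degree_centrality": [dc[n] for n in nodes],
        "betweenness": [bet[n] for n in nodes],
        "closeness": [clo[n] for n in nodes],
        "eigenvector": [eig[n] for n in nodes],
    }, index=pd.Index(nodes, name="node"))


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    density: float
    avg_clustering: float
    composition: dict[str, float]          # type -> percentage, 1 d.p.
    hub_compounds: list[tuple[str, int]]   # degree >= threshold, desc
    hub_compound_fraction: Optional[float]
    powerlaw_r2: Optional[float] = None


def powerlaw_fit_r2(sizes: list[int]) -> Optional[float]:
    """R^2 of the least-squares line of log(size) vs log(rank) over
    descending community sizes; None when fewer than 2 positive sizes."""
    sizes = sorted((s for s in sizes if s > 0), reverse=True)
    if len(sizes) < 2:
        return None
    x = np.log(np.arange(1, len(sizes) + 1, dtype=float))
    y = np.log(np.asarray(sizes, dtype=float))
    res = sps.linregress(x, y)
    return float(res.rvalue ** 2)


def topology_summary(G: nx.Graph, hub_degree: int = 5,
                     partition: Optional[dict] = None) -> TopologySummary:
    """Global topology metrics, node-type composition and hub compounds.

    Hub compounds are compounds with degree >= ``hub_degree`` (distinct
    targets plus plant links), a proxy for multi-target agents.  When a
    community ``partition`` (node -> community id) is supplied, the power-law
    R^2 of the community-size distribution is included.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty network")
    n = G.number_of_nodes()
    dens = density(G) if n >= 2 else 0.0
    clus = nx.average_clustering(G) if n > 0 else 0.0
    type_counts = Counter(d["entity_type"] for _, d in G.nodes(data=True))
    composition = {t: round(100.0 * type_counts.get(t, 0) / n, 1)
                   for t in NODE_TYPES}
    compounds = [(m, G.degree(m)) for m, d in G.nodes(data=True)
                 if d["entity_type"] == "compound"]
    hubs = sorted(((m, dg) for m, dg in compounds if dg >= hub_degree),
                  key=lambda t: (-t[1], t[0]))
    hub_frac = len(hubs) / len(compounds) if compounds else None
    r2 = None
    if partition is not None:
        r2 = powerlaw_fit_r2(list(Counter(partition.values()).values()))
    return TopologySummary(n_nodes=n, n_edges=G.number_of_edges(),
                           density=dens, avg_clustering=clus,
                           composition=composition, hub_compounds=hubs,
                           hub_compound_fraction=hub_frac, powerlaw_r2=r2)
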