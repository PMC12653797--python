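"""Community detection, modularity and configuration-model significance.

The null ensemble preserves both the degree sequence and the layered typing
of the tripartite graph: randomization is by double-edge swaps constrained
within each layer (gene-compound edges swap only with gene-compound edges,
compound-plant only with compound-plant).  Swapping the right-hand endpoints
of two oriented within-layer edges can never create a same-type or
gene-plant edge, so the tripartite invariant holds by construction; proposed
swaps that would create a parallel edge are rejected, keeping the graph
simple.  This is a stricter null than unconstrained stub matching and is the
appropriate ensemble for layered networks.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterator, Optional

import networkx as nx
import numpy as np

from .network import LAYER_CP, LAYER_GC

logger = logging.getLogger("phytonet.communities")

NULL_METRICS = ("modularity", "avg_clustering", "avg_path_length")


@dataclass
class Partition:
    assignment: dict
    modularity_q: float
    resolution: float
    seed: int

    def communities(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for n, c in self.assignment.items():
            out.setdefault(c, set()).add(n)
        return out


def modularity(G: nx.Graph, assignment: dict) -> float:
    """Newman-Girvan modularity Q = sum_c [e_c/m - (d_c/2m)^2] for an
    unweighted simple graph and a complete node -> community assignment."""
    m = G.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    missing = [n for n in G.nodes() if n not in assignment]
    if missing:
        raise ValueError(f"assignment missing {len(missing)} nodes, "
                         f"e.g. {missing[0]!r}")
    e_c: Counter = Counter()
    d_c: Counter = Counter()
    for u, v in G.edges():
        if assignment[u] == assignment[v]:
            e_c[assignment[u]] += 1
    for n, deg in G.degree():
        d_c[assignment[n]] += deg
    return float(sum(e_c[c] / m - (d_c[c] / (2.0 * m)) ** 2 for c in d_c))


def _canonical_assignment(communities: list[set]) -> dict:
    """Relabel communities 0..k-1 by their smallest member (as string) so
    equal partitions always serialize identically."""
    ordered = sorted(communities, key=lambda c: min(map(str, c)))
    return {n: i for i, comm in enumerate(ordered) for n in comm}


def louvain_partition(G: nx.Graph, resolution: float = 1.0,
                      seed: int = 0) -> Partition:
    """Seeded Louvain community detection with canonical labels.

    A graph with no edges yields singleton communities and Q = 0 by
    convention (modularity is otherwise undefined there).
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if G.number_of_edges() == 0:
        assignment = {n: i for i, n in enumerate(sorted(G.nodes(), key=str))}
        return Partition(assignment, 0.0, resolution, seed)
    comms = nx.community.louvain_communities(G, resolution=resolution,
                                             seed=int(seed))
    assignment = _canonical_assignment([set(c) for c in comms])
    return Partition(assignment, modularity(G, assignment), resolution, seed)


def _layer_edges(G: nx.Graph) -> dict[str, list[tuple]]:
    """Oriented within-layer edge lists: gene-compound edges as
    (gene, compound), compound-plant edges as (compound, plant)."""
    left_type = {LAYER_GC: "gene", LAYER_CP: "compound"}
    layers: dict[str, list[tuple]] = {LAYER_GC: [], LAYER_CP: []}
    for u, v, d in G.edges(data=True):
        layer = d["layer"]
        lt = left_type[layer]
        if G.nodes[u]["entity_type"] == lt:
            layers[layer].append((u, v))
        else:
            layers[layer].append((v, u))
    return layers


def _swap_edges(edges: list[tuple], rng: np.random.Generator,
                swaps_per_edge: int) -> list[tuple]:
    """Degree-preserving double-edge swaps on one oriented edge list.

    (a,b),(c,d) -> (a,d),(c,b); proposals re-creating an existing edge or
    touching identical endpoints are rejected, preserving simplicity.
    """
    ne = len(edges)
    if ne < 2:
        return list(edges)
    edges = list(edges)
    present = set(edges)
    attempts = swaps_per_edge * ne
    idx = rng.integers(0, ne, size=(attempts, 2))
    for i, j in idx:
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == c or b == d:
            continue
        new1, new2 = (a, d), (c, b)
        if new1 in present or new2 in present:
            continue
        present.discard(edges[i])
        present.discard(edges[j])
        present.add(new1)
        present.add(new2)
        edges[i], edges[j] = new1, new2
    return edges


def randomize(G: nx.Graph, n_iter: int, seed: int = 0,
              swaps_per_edge: int = 10) -> Iterator[nx.Graph]:
    """Stream ``n_iter`` degree- and type-preserving randomized replicates.

    Each replicate keeps every node (with its entity_type), every node's
    degree, and the per-layer edge counts; only the wiring within each layer
    changes.  A layer with fewer than 2 edges cannot be rewired and is left
    intact (with a logged warning, once).
    """
    rng = np.random.default_rng(seed)
    layers = _layer_edges(G)
    for layer, edges in layers.items():
        if 0 < len(edges) < 2:
            logger.warning("layer %s has %d edge(s); cannot randomize, "
                           "replicates keep it unchanged", layer, len(edges))
    for _ in range(n_iter):
        H = nx.Graph()
        H.add_nodes_from(G.nodes(data=True))
        for layer, edges in layers.items():
            for u, v in _swap_edges(edges, rng, swaps_per_edge):
                H.add_edge(u, v, layer=layer, weight=1)
        yield H


@dataclass
class NullEnsemble:
    metric_name: str
    samples: list[float]
    observed: float
    empirical_p: float
    convergence: list[tuple[int, float]]   # (checkpoint iteration, CV)
    seed: int
    n_iter: int
    tail: str = "greater"

    def max_cv_from(self, checkpoint: int) -> float:
        vals = [cv for t, cv in self.convergence if t >= checkpoint]
        if not vals:
            raise ValueError(f"no checkpoints at or beyond {checkpoint}")
        return max(vals)

    def to_json_dict(self, include_samples: bool = True) -> dict:
        d = {"metric_name": self.metric_name, "observed": self.observed,
             "empirical_p": self.empirical_p, "n_iter": self.n_iter,
             "seed": self.seed, "tail": self.tail,
             "null_mean": float(np.mean(self.samples)),
             "null_std": float(np.std(self.samples)),
             "convergence": [[t, cv] for t, cv in self.convergence]}
        if include_samples and len(self.samples) <= 10_000:
            d["samples"] = list(map(float, self.samples))
        return d


def _avg_path_length(G: nx.Graph) -> float:
    """Mean shortest-path length over connected (reachable) node pairs."""
    total = 0
    pairs = 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
    if pairs == 0:
        return 0.0
    return total / pairs


def empirical_p(samples: np.ndarray, observed: float,
                tail: str = "greater") -> float:
    """(+1)-corrected permutation p-value; always in [1/(n+1), 1]."""
    n = len(samples)
    if tail == "greater":
        return float((1 + np.sum(samples >= observed)) / (1 + n))
    if tail == "less":
        return float((1 + np.sum(samples <= observed)) / (1 + n))
    if tail == "two-sided":
        lo = (1 + np.sum(samples <= observed)) / (1 + n)
        hi = (1 + np.sum(samples >= observed)) / (1 + n)
        return float(min(1.0, 2.0 * min(lo, hi)))
    raise ValueError(f"unknown tail {tail!r}")


def convergence_trajectory(samples: list[float],
                           checkpoint_every: int = 100) -> list[tuple[int, float]]:
    """Cumulative-mean stability trajectory.

    At checkpoint t the CV is the population std of the cumulative means
    recorded at checkpoints in (t/2, t], divided by |cumulative mean at t|.
    """
    n = len(samples)
    csum = np.cumsum(samples)
    checkpoints = list(range(checkpoint_every, n + 1, checkpoint_every))
    if not checkpoints or checkpoints[-1] != n:
        checkpoints.append(n)
    cmean = {t: csum[t - 1] / t for t in checkpoints}
    out = []
    for t in checkpoints:
        window = [cmean[u] for u in checkpoints if t / 2 < u <= t]
        denom = abs(cmean[t])
        cv = float(np.std(window) / denom) if denom > 0 else float("inf")
        out.append((t, cv))
    return out


def null_test(G: nx.Graph, metric_name: str, n_iter: int = 1000,
              seed: int = 0, tail: str = "greater",
              resolution: float = 1.0,
              swaps_per_edge: int = 10) -> NullEnsemble:
    """Compare an observed topology metric against the layer-constrained
    configuration-model null.

    For ``modularity`` each replicate is re-partitioned with seeded Louvain
    before scoring, so the null distribution reflects the best modularity a
    degree-matched random network can achieve.  The default upper tail asks
    whether the observed network is *more* structured than random.
    """
    if n_iter < 10:
        raise ValueError("n_iter < 10 gives a meaningless null")
    if metric_name not in NULL_METRICS:
        raise ValueError(f"unknown metric {metric_name!r}; "
                         f"choose from {NULL_METRICS}")
    ss = np.random.SeedSequence(seed)
    s_louvain, s_swap = ss.spawn(2)
    louvain_seeds = s_louvain.generate_state(n_iter + 1)

    def metric(g: nx.Graph, lseed: int) -> float:
        if metric_name == "modularity":
            if g.number_of_edges() == 0:
                return 0.0
            return louvain_partition(g, resolution=resolution,
                                     seed=int(lseed % 2**31)).modularity_q
        if metric_name == "avg_clustering":
            return float(nx.average_clustering(g))
        return _avg_path_length(g)

    observed = metric(G, louvain_seeds[-1])
    rng_seed = int(s_swap.generate_state(1)[0])
    samples = [metric(H, louvain_seeds[i])
               for i, H in enumerate(randomize(G, n_iter, seed=rng_seed,
                                               swaps_per_edge=swaps_per_edge))]
    arr = np.asarray(samples, dtype=float)
    ens = NullEnsemble(metric_name=metric_name, samples=samples,
                       observed=observed,
                       empirical_p=empirical_p(arr, observed, tail),
                       convergence=convergence_trajectory(samples),
                       seed=seed, n_iter=n_iter, tail=tail)
    logger.info("null_test %s: observed=%.4f null=%.4f+/-%.4f p=%.4g",
                metric_name, observed, arr.mean(), arr.std(), ens.empirical_p)
    return ens
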