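"""Publication-quality figure generation (300 DPI PNG).

Color scheme is fixed by entity type: genes blue, compounds green, plants
pink.  Network layouts use a seeded spring embedding whose repulsion adapts
to graph density (repulsion ~ 1/sqrt(density), floored), so sparse graphs
spread out and dense ones stay compact.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import matplotlib
import matplotlib.pyplot as plt
import networkx as nx
import numpy as np
import pandas as pd
import seaborn as sns

from .enrichment import EnrichmentRecord, records_to_frame
from .network import NODE_TYPES

logger = logging.getLogger("phytonet.viz")

TYPE_COLORS = {"gene": "#1f77b4", "compound": "#2ca02c", "plant": "#f781bf"}


@dataclass(frozen=True)
class FigureStyle:
    dpi: int = 300
    node_colors: dict = field(default_factory=lambda: dict(TYPE_COLORS))
    layout_seed: int = 0
    max_labeled_nodes: int = 300


@dataclass
class RenderResult:
    path: Optional[Path]
    n_items: int


def compute_layout(G: nx.Graph, style: FigureStyle = FigureStyle()) -> dict:
    """Seeded spring layout with density-adaptive repulsion."""
    n = G.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    dens = nx.density(G) if n > 1 else 1.0
    k = (1.0 / math.sqrt(n)) / math.sqrt(max(dens, 1e-3))
    return nx.spring_layout(G, k=k, seed=style.layout_seed)


def render_network(G: nx.Graph, out_path: str | Path,
                   partition: Optional[dict] = None,
                   style: FigureStyle = FigureStyle()) -> RenderResult:
    """Draw the typed network; community membership (if given) maps to node
    border shading, entity type to fill color.  Labels are suppressed above
    ``max_labeled_nodes`` and for very large graphs (> 5000 nodes, with a
    warning)."""
    out_path = Path(out_path)
    n = G.number_of_nodes()
    if n == 0:
        raise ValueError("empty network")
    if n > 5000:
        logger.warning("network has %d nodes; labels suppressed", n)
    pos = compute_layout(G, style)
    fig, ax = plt.subplots(figsize=(8, 8))
    colors = [style.node_colors[G.nodes[v]["entity_type"]] for v in G.nodes()]
    sizes = [40 + 12 * G.degree(v) for v in G.nodes()]
    nx.draw_networkx_edges(G, pos, ax=ax, alpha=0.3, width=0.6)
    if partition:
        comms = sorted(set(partition.values()))
        cmap = matplotlib.colormaps["tab20"]
        edgecolors = [cmap(comms.index(partition.get(v, comms[0])) % 20)
                      for v in G.nodes()]
        nx.draw_networkx_nodes(G, pos, ax=ax, node_color=colors,
                               node_size=sizes, edgecolors=edgecolors,
                               linewidths=1.5)
    else:
        nx.draw_networkx_nodes(G, pos, ax=ax, node_color=colors,
                               node_size=sizes)
    if n <= min(style.max_labeled_nodes, 5000):
        nx.draw_networkx_labels(G, pos, ax=ax, font_size=6)
    handles = [plt.Line2D([], [], marker="o", ls="", color=c, label=t)
               for t, c in style.node_colors.items()]
    ax.legend(handles=handles, loc="upper right", frameon=False)
    ax.set_axis_off()
    fig.savefig(out_path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return RenderResult(out_path, n)


def render_heatmap(incidence: pd.DataFrame, out_path: str | Path,
                   style: FigureStyle = FigureStyle()) -> RenderResult:
    """Compound x gene incidence heatmap."""
    if incidence.empty:
        logger.info("empty incidence matrix; heatmap skipped")
        return RenderResult(None, 0)
    out_path = Path(out_path)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * incidence.shape[1] + 2),
                 max(3, 0.25 * incidence.shape[0] + 1)))
    sns.heatmap(incidence, ax=ax, cmap="viridis", cbar_kws={"shrink": 0.6})
    ax.set_xlabel("gene")
    ax.set_ylabel("compound")
    fig.savefig(out_path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return RenderResult(out_path, incidence.size)


def render_bubble(records: Sequence[EnrichmentRecord], out_path: str | Path,
                  query_size: Optional[int] = None,
                  style: FigureStyle = FigureStyle()) -> RenderResult:
    """Bubble plot: x = overlap ratio k/n, bubble size = k, color =
    adjusted p on a log scale.  Records with p_adj = 1 are drawn, not
    dropped; an all-empty record list is skipped with a log entry."""
    recs = [r for r in records if r.overlap_k is not None]
    if not recs:
        logger.info("no ORA records; bubble plot skipped")
        return RenderResult(None, 0)
    out_path = Path(out_path)
    n = query_size or max(r.overlap_k for r in recs) or 1
    x = [r.overlap_k / n for r in recs]
    sizes = [30 + 25 * r.overlap_k for r in recs]
    color = [-np.log10(max(r.p_adj, 1e-300)) for r in recs]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(recs))))
    sc = ax.scatter(x, range(len(recs)), s=sizes, c=color, cmap="plasma")
    ax.set_yticks(range(len(recs)))
    ax.set_yticklabels([r.set_name for r in recs], fontsize=7)
    ax.set_xlabel("overlap ratio k/n")
    fig.colorbar(sc, ax=ax, label="-log10 adjusted p")
    fig.savefig(out_path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return RenderResult(out_path, len(recs))


def render_bars(records: Sequence[EnrichmentRecord], out_path: str | Path,
                top: int = 20,
                style: FigureStyle = FigureStyle()) -> RenderResult:
    """Horizontal bars of -log10 adjusted p for the top sets (ascending
    p_adj, at most ``top`` shown)."""
    recs = sorted(records, key=lambda r: (r.p_adj, r.set_name))[:top]
    if not recs:
        logger.info("no enrichment records; bar chart skipped")
        return RenderResult(None, 0)
    out_path = Path(out_path)
    vals = [-np.log10(max(r.p_adj, 1e-300)) for r in recs]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(recs))))
    ax.barh([r.set_name for r in recs][::-1], vals[::-1], color="#2ca02c")
    ax.set_xlabel("-log10 adjusted p")
    fig.savefig(out_path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return RenderResult(out_path, len(recs))


def render_centrality_panels(profile: pd.DataFrame, out_path: str | Path,
                             style: FigureStyle = FigureStyle()) -> RenderResult:
    """2x2 histogram panels of degree, betweenness, closeness and
    eigenvector centrality."""
    if profile.empty:
        logger.info("empty centrality profile; panels skipped")
        return RenderResult(None, 0)
    out_path = Path(out_path)
    cols = ["degree", "betweenness", "closeness", "eigenvector"]
    fig, axes = plt.subplots(2, 2, figsize=(8, 6))
    for ax, col in zip(axes.ravel(), cols):
        ax.hist(profile[col], bins=20, color="#1f77b4", alpha=0.8)
        ax.set_title(col)
    fig.tight_layout()
    fig.savefig(out_path, dpi=style.dpi, bbox_inches="tight")
    plt.close(fig)
    return RenderResult(out_path, len(profile))


def incidence_matrix(table) -> pd.DataFrame:
    """Compound x gene 0/1 incidence from a relationship table."""
    cg = table.compound_genes()
    compounds = sorted(cg)
    genes = sorted(set().union(*cg.values())) if cg else []
    mat = pd.DataFrame(0, index=compounds, columns=genes, dtype=int)
    for c, gs in cg.items():
        for g in gs:
            mat.loc[c, g] = 1
    return mat
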