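"""Hierarchical run outputs, graph serialization, reports and provenance.

Every run populates a fixed four-directory tree under the run root::

    1_network/               GEXF + node-link JSON graphs, topology tables
    2_figures/visualization/ PNG figures at 300 DPI
    3_gene_selection/        ranked gene table, per-entity gene lists
    4_enrichment/            per-entity enrichment tables

plus run.log, report.md and manifest.json at the root.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import networkx as nx

from . import __version__
from .network import assert_tripartite

logger = logging.getLogger("phytonet.output")

SUBDIRS = ("1_network", "2_figures/visualization", "3_gene_selection",
           "4_enrichment")


@dataclass
class RunDirs:
    root: Path
    network: Path
    figures: Path
    gene_selection: Path
    enrichment: Path


def init_run(output_root: str | Path, overwrite: bool = False) -> RunDirs:
    """Create the output tree; refuses an existing non-empty root unless
    ``overwrite`` is set.  The root is resolved to an absolute path."""
    root = Path(output_root).resolve()
    if root.exists():
        if any(root.iterdir()) and not overwrite:
            raise FileExistsError(f"{root} exists and is not empty; "
                                  "pass overwrite to reuse it")
    root.mkdir(parents=True, exist_ok=True)
    if not (root.is_dir() and _writable(root)):
        raise PermissionError(f"{root} is not a writable directory")
    for sub in SUBDIRS:
        (root / sub).mkdir(parents=True, exist_ok=True)
    return RunDirs(root=root,
                   network=root / "1_network",
                   figures=root / "2_figures" / "visualization",
                   gene_selection=root / "3_gene_selection",
                   enrichment=root / "4_enrichment")


def _writable(path: Path) -> bool:
    probe = path / ".phytonet_probe"
    try:
        probe.touch()
        probe.unlink()
        return True
    except OSError:
        return False


def write_graph(G: nx.Graph, directory: str | Path,
                stem: str = "network") -> tuple[Path, Path]:
    """Serialize the network to GEXF 1.2 and node-link JSON; an invalid
    (non-tripartite) graph is a hard error, never emitted."""
    assert_tripartite(G)
    directory = Path(directory)
    gexf = directory / f"{stem}.gexf"
    jsn = directory / f"{stem}.json"
    nx.write_gexf(G, gexf, version="1.2draft")
    data = nx.node_link_data(G, edges="edges")
    jsn.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n",
                   encoding="utf-8")
    return gexf, jsn


def read_gexf_network(path: str | Path) -> nx.Graph:
    G = nx.read_gexf(path)
    H = nx.Graph()
    for n, d in G.nodes(data=True):
        H.add_node(n, entity_type=d["entity_type"])
    for u, v, d in G.edges(data=True):
        H.add_edge(u, v, layer=d["layer"], weight=int(d.get("weight", 1)))
    assert_tripartite(H)
    return H


def read_json_network(path: str | Path) -> nx.Graph:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    G = nx.node_link_graph(data, edges="edges")
    assert_tripartite(G)
    return G


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    timestamp: str = ""
    tool_version: str = __version__
    inputs: dict = field(default_factory=dict)       # path -> sha256
    parameters: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)      # relpath -> sha256
    skipped: dict = field(default_factory=dict)      # stage -> reason

    def record_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = sha256_file(path)

    def inventory(self, root: Path) -> None:
        self.outputs = {}
        for p in sorted(root.rglob("*")):
            if p.is_file() and p.name not in ("manifest.json", "run.log"):
                self.outputs[str(p.relative_to(root))] = sha256_file(p)

    def write(self, path: str | Path) -> None:
        self.timestamp = self.timestamp or datetime.now(timezone.utc).isoformat()
        Path(path).write_text(
            json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)
            + "\n", encoding="utf-8")


def write_report(sections: dict[str, str], path: str | Path,
                 title: str = "Analysis report") -> Path:
    """Markdown report with one section per completed stage."""
    path = Path(path)
    lines = [f"# {title}", ""]
    for heading, body in sections.items():
        lines += [f"## {heading}", "", body.rstrip(), ""]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
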