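"""One-shot analysis pipeline: validation -> network -> communities/null ->
enrichment -> figures -> report.

Mandatory stages (validation, network) abort the run on failure; optional
stages (GSVA without an expression matrix, figures) are skipped with a
reason recorded in the manifest.
"""

from __future__ import annotations

import json
import logging
import re
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from . import communities, enrichment, io_validation, network, output, viz
from .config import RunConfig

logger = logging.getLogger("phytonet.pipeline")


def _slug(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", name).strip("_").lower() or "x"


def _setup_logging(root: Path, level: str) -> None:
    root_logger = logging.getLogger("phytonet")
    root_logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    for h in list(root_logger.handlers):
        root_logger.removeHandler(h)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    fh = logging.FileHandler(root / "run.log", encoding="utf-8")
    fh.setFormatter(fmt)
    sh = logging.StreamHandler(sys.stderr)
    sh.setFormatter(fmt)
    root_logger.addHandler(fh)
    root_logger.addHandler(sh)


def run(cfg: RunConfig) -> int:
    """Execute the full pipeline; returns a process exit status (0 = all
    mandatory stages succeeded)."""
    seed = cfg.seed
    if seed is None:
        seed = int(np.random.SeedSequence().generate_state(1)[0] % 2**31)
    ss = np.random.SeedSequence(seed)
    seed_louvain, seed_null, seed_gsea, seed_layout = [
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    dirs = output.init_run(cfg.output_root, overwrite=cfg.overwrite)
    _setup_logging(dirs.root, cfg.log_level)
    manifest = output.RunManifest(parameters=cfg.to_dict(),
                                  seeds={"seed": seed,
                                         "louvain": seed_louvain,
                                         "null": seed_null,
                                         "gsea": seed_gsea,
                                         "layout": seed_layout})
    sections: dict[str, str] = {}

    # --- validation (mandatory) -------------------------------------------
    raw = io_validation.parse_relationship_csv(cfg.relationships)
    manifest.record_input(cfg.relationships)
    report = io_validation.validate(raw)
    report.to_json(dirs.root / "validation_report.json")
    if report.status == "fail":
        logger.error("validation failed: %s", report.errors)
        manifest.write(dirs.root / "manifest.json")
        return 2
    table, dup = io_validation.clean(raw)
    stats = io_validation.relationship_stats(table)
    sections["Validation"] = (
        f"- status: **{report.status}**, rows: {report.n_rows}, "
        f"invalid fraction: {report.invalid_fraction:.3f}\n"
        f"- duplicates removed: {dup['duplicate_count']}, rows without gene "
        f"dropped: {dup['dropped_no_gene']}\n"
        f"- orphan gene fraction: {stats.orphan_gene_fraction:.3f}; "
        f"multi-compound gene fraction: "
        f"{stats.multi_compound_gene_fraction}; cross-plant compound "
        f"fraction: {stats.cross_plant_compound_fraction}")

    # --- network (mandatory) ----------------------------------------------
    net = network.build_network(table,
                                weight_by_frequency=cfg.weight_by_frequency)
    output.write_graph(net, dirs.network)
    profile = network.centralities(net)
    profile.to_csv(dirs.network / "centralities.csv")
    partition = communities.louvain_partition(net, resolution=cfg.resolution,
                                              seed=seed_louvain)
    topo = network.topology_summary(net, hub_degree=cfg.hub_degree,
                                    partition=partition.assignment)
    pd.Series({
        "n_nodes": topo.n_nodes, "n_edges": topo.n_edges,
        "density": topo.density, "avg_clustering": topo.avg_clustering,
        "modularity": partition.modularity_q,
        "n_communities": len(set(partition.assignment.values())),
        "powerlaw_r2": topo.powerlaw_r2,
        **{f"pct_{t}": v for t, v in topo.composition.items()},
    }).to_csv(dirs.network / "network_statistics.csv", header=False)
    sections["Topology"] = (
        f"- {topo.n_nodes} nodes / {topo.n_edges} edges, density "
        f"{topo.density:.4f}, avg clustering {topo.avg_clustering:.3f}\n"
        f"- composition: " + ", ".join(f"{t} {v}%" for t, v in
                                       topo.composition.items()) + "\n"
        f"- hub compounds (degree >= {cfg.hub_degree}): "
        f"{len(topo.hub_compounds)}")

    # --- null-model significance ------------------------------------------
    ens = communities.null_test(net, "modularity", n_iter=cfg.n_random,
                                seed=seed_null, resolution=cfg.resolution)
    (dirs.network / "null_modularity.json").write_text(
        json.dumps(ens.to_json_dict(), indent=2) + "\n", encoding="utf-8")
    pd.DataFrame(ens.convergence, columns=["iteration", "cv"]).to_csv(
        dirs.network / "null_modularity_convergence.csv", index=False)
    sections["Communities"] = (
        f"- Louvain modularity Q = {partition.modularity_q:.4f} "
        f"({len(set(partition.assignment.values()))} communities)\n"
        f"- configuration-model null ({ens.n_iter} replicates): "
        f"Q_null = {np.mean(ens.samples):.4f} +/- {np.std(ens.samples):.4f}, "
        f"empirical p = {ens.empirical_p:.4g}")

    # --- gene selection ----------------------------------------------------
    ranking = enrichment.compound_degree_ranking(table)
    pd.DataFrame(ranking, columns=["gene", "n_compounds"]).to_csv(
        dirs.gene_selection / "ranked_genes.csv", index=False)
    entity_genes = {
        "compounds": {c: sorted(g) for c, g in table.compound_genes().items()},
        "plants": {p: sorted(g) for p, g in table.plant_genes().items()},
    }
    (dirs.gene_selection / "entity_gene_lists.json").write_text(
        json.dumps(entity_genes, indent=1, sort_keys=True) + "\n",
        encoding="utf-8")

    # --- enrichment --------------------------------------------------------
    collections = []
    for gmt_path in cfg.gene_sets:
        collections.append(enrichment.read_gmt(gmt_path))
        manifest.record_input(gmt_path)
    enr_lines = []
    first_global_records: list = []
    for coll in collections:
        label = _slug(coll.database_label)
        # background universe: table genes plus every collection member, so
        # the global query is a proper subset and the test is informative
        background = table.genes() | {g for s in coll for g in s.members}
        if cfg.run_ora:
            bundles = enrichment.entity_enrichment(
                table, coll, background=background,
                min_size=cfg.ora_min_size)
            for b in bundles:
                if b.skipped:
                    manifest.skipped[f"ora:{label}:{b.entity_id}"] = \
                        b.skip_reason or "skipped"
                    continue
                if b.entity_type == "global" and not first_global_records:
                    first_global_records = b.records
                df = enrichment.records_to_frame(b.records)
                df.to_csv(dirs.enrichment /
                          f"{b.entity_type}_{_slug(b.entity_id)}_{label}_ora.csv",
                          index=False)
            n_sig = sum(r.p_adj < cfg.fdr_threshold
                        for b in bundles if b.entity_type == "global"
                        for r in b.records)
            enr_lines.append(f"- ORA [{label}]: {n_sig} sets with "
                             f"FDR < {cfg.fdr_threshold} (global)")
        if cfg.run_gsea:
            gsea_recs = enrichment.gsea_preranked(
                ranking, coll, weight=cfg.gsea_weight, n_perm=cfg.n_perm,
                min_size=cfg.gsea_min_size, seed=seed_gsea)
            enrichment.records_to_frame(gsea_recs).to_csv(
                dirs.enrichment / f"global_{label}_gsea.csv", index=False)
            n_sig = sum(abs(r.nes) > cfg.nes_threshold
                        and r.p_adj < cfg.gsea_fdr_threshold
                        for r in gsea_recs)
            enr_lines.append(f"- GSEA [{label}]: {n_sig} sets with |NES| > "
                             f"{cfg.nes_threshold} and FDR < "
                             f"{cfg.gsea_fdr_threshold}")
        if cfg.run_gsva:
            if cfg.expression is None:
                manifest.skipped[f"gsva:{label}"] = "no expression matrix"
                enr_lines.append(f"- GSVA [{label}]: skipped "
                                 "(no expression matrix)")
            else:
                expr = pd.read_csv(cfg.expression, sep=None, engine="python",
                                   index_col=0)
                manifest.record_input(cfg.expression)
                scores = enrichment.gsva(expr, coll,
                                         min_size=cfg.gsva_min_size,
                                         max_size=cfg.gsva_max_size)
                scores.to_csv(dirs.enrichment / f"gsva_{label}.csv")
                enr_lines.append(f"- GSVA [{label}]: {scores.shape[0]} sets x "
                                 f"{scores.shape[1]} samples")
    if len(table.plants()) >= 2:
        shared = enrichment.shared_target_analysis(table)
        (dirs.gene_selection / "shared_targets.json").write_text(
            json.dumps({"core": sorted(shared.core),
                        "unique": {p: sorted(v) for p, v in
                                   shared.unique.items()},
                        "pairwise": {f"{a}|{b}": sorted(v) for (a, b), v in
                                     shared.pairwise.items()}},
                       indent=1) + "\n", encoding="utf-8")
        enr_lines.append(f"- shared targets: {len(shared.core)} genes hit by "
                         "compounds from every plant")
    sections["Enrichment"] = "\n".join(enr_lines) if enr_lines else \
        "- no gene-set collections supplied"

    # --- figures (optional) -----------------------------------------------
    if cfg.skip_figures:
        manifest.skipped["figures"] = "disabled by configuration"
    else:
        style = viz.FigureStyle(layout_seed=seed_layout)
        viz.render_network(net, dirs.figures / "global_network.png",
                           partition=partition.assignment, style=style)
        viz.render_heatmap(viz.incidence_matrix(table),
                           dirs.figures / "global_heatmap.png", style=style)
        viz.render_centrality_panels(
            profile, dirs.figures / "global_centrality.png", style=style)
        if first_global_records:
            viz.render_bubble(first_global_records,
                              dirs.figures / "global_bubble.png",
                              query_size=len(table.genes()), style=style)
            viz.render_bars(first_global_records,
                            dirs.figures / "global_bars.png", style=style)

    # --- report and manifest ----------------------------------------------
    output.write_report(sections, dirs.root / "report.md")
    manifest.inventory(dirs.root)
    manifest.write(dirs.root / "manifest.json")
    logger.info("run complete: %s", dirs.root)
    return 0
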