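"""Synthetic relationship tables, gene-set collections and expression
matrices with recorded ground truth.

The default specification reproduces the structure of a small multi-herb
screening dataset: 111 genes, 32 compounds and 3 plants, with 32.4% of
compounds shared across plants, 28.7% of genes hit by multiple compounds
and 8.1% orphan genes.  Counts are placed exactly (rounded targets), not in
expectation, so that every downstream statistic is deterministic given the
seed.  One integer seed drives all substreams through
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet, GeneSetCollection, write_gmt
from .io_validation import RelationshipTable, Row

logger = logging.getLogger("phytonet.fixtures")


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    n_genes: int = 111
    n_compounds: int = 32
    n_plants: int = 3
    cross_plant_compound_fraction: float = 0.324
    multi_compound_gene_fraction: float = 0.287
    orphan_gene_fraction: float = 0.081
    #: (size, concentration): concentration is the fraction of members drawn
    #: from the multi-compound (top-of-ranking) stratum
    planted_sets: tuple[tuple[int, float], ...] = ((20, 0.8),)
    common_core_size: int = 10
    seed: int = 0


@dataclass
class FixtureTruth:
    orphan_genes: tuple[str, ...]
    cross_plant_compounds: tuple[str, ...]
    multi_compound_genes: tuple[str, ...]
    common_core: tuple[str, ...]
    planted_set_members: dict[str, tuple[str, ...]]
    effect_ranks: dict[str, tuple[int, ...]]   # ranking positions, 0-based

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2,
                                         default=list) + "\n",
                              encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FixtureTruth":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(orphan_genes=tuple(d["orphan_genes"]),
                   cross_plant_compounds=tuple(d["cross_plant_compounds"]),
                   multi_compound_genes=tuple(d["multi_compound_genes"]),
                   common_core=tuple(d["common_core"]),
                   planted_set_members={k: tuple(v) for k, v in
                                        d["planted_set_members"].items()},
                   effect_ranks={k: tuple(v) for k, v in
                                 d["effect_ranks"].items()})


def _names(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_relationships(spec: FixtureSpec = FixtureSpec(),
                           path: Optional[str | Path] = None
                           ) -> tuple[RelationshipTable, FixtureTruth]:
    """Construct a relationship table hitting the spec's entity counts and
    fractions exactly; optionally write it as CSV (byte-stable given seed).

    Layout: ``round(orphan_fraction * n_genes)`` genes get no compound;
    ``round(multi_fraction * n_genes)`` genes get >= 2 compounds, of which
    the first ``common_core_size`` are hit by one single-plant compound per
    plant (the planted common core recovered by shared-target analysis);
    every remaining connected gene gets exactly one compound.
    ``round(cross_fraction * n_compounds)`` compounds are assigned two
    plants, the rest one, with the first ``n_plants`` compounds pinned
    round-robin so every plant is represented.
    """
    for f in (spec.cross_plant_compound_fraction,
              spec.multi_compound_gene_fraction, spec.orphan_gene_fraction):
        if not 0 <= f <= 1:
            raise FixtureError(f"fraction {f} outside [0, 1]")
    if min(spec.n_genes, spec.n_compounds, spec.n_plants) < 1:
        raise FixtureError("entity counts must be positive")
    n_orphan = round(spec.orphan_gene_fraction * spec.n_genes)
    n_multi = round(spec.multi_compound_gene_fraction * spec.n_genes)
    n_cross = round(spec.cross_plant_compound_fraction * spec.n_compounds)
    n_connected = spec.n_genes - n_orphan
    core_size = min(spec.common_core_size, n_multi) if spec.n_plants >= 2 else 0
    if n_connected < n_multi:
        raise FixtureError(f"orphan ({n_orphan}) + multi-compound ({n_multi}) "
                           f"targets exceed {spec.n_genes} genes")
    if spec.n_plants >= 2 and n_cross > spec.n_compounds:
        raise FixtureError("more cross-plant compounds than compounds")
    if spec.n_compounds < spec.n_plants:
        raise FixtureError("need at least one compound per plant")

    ss = np.random.SeedSequence(spec.seed)
    rng_assign, rng_plant, rng_gmt = [np.random.default_rng(s)
                                      for s in ss.spawn(3)]

    genes = _names("GENE", spec.n_genes)
    compounds = _names("CMP", spec.n_compounds)
    plants = _names("PLANT", spec.n_plants)

    perm = rng_assign.permutation(spec.n_genes)
    orphans = [genes[i] for i in perm[:n_orphan]]
    multi = [genes[i] for i in perm[n_orphan:n_orphan + n_multi]]
    singles = [genes[i] for i in perm[n_orphan + n_multi:]]
    core = multi[:core_size]

    # plant assignment: pin one single-plant compound per plant, then draw
    compound_plants: dict[str, tuple[str, ...]] = {}
    if spec.n_plants >= 2:
        cross_set = set(
            rng_plant.choice(compounds[spec.n_plants:], size=n_cross,
                             replace=False)) if n_cross else set()
        if n_cross > spec.n_compounds - spec.n_plants:
            raise FixtureError("not enough compounds to pin one single-plant "
                               "compound per plant")
    else:
        cross_set = set()
    for i, c in enumerate(compounds):
        if i < spec.n_plants:
            compound_plants[c] = (plants[i],)
        elif c in cross_set:
            pair = rng_plant.choice(spec.n_plants, size=2, replace=False)
            compound_plants[c] = tuple(plants[j] for j in sorted(pair))
        else:
            compound_plants[c] = (plants[int(rng_plant.integers(spec.n_plants))],)

    single_plant_compound = {plants[i]: compounds[i]
                             for i in range(spec.n_plants)}

    all_plants = set(plants)

    def _covers_all(cs: list[str]) -> bool:
        return set().union(*(compound_plants[c] for c in cs)) == all_plants

    gene_compounds: dict[str, list[str]] = {}
    for g in core:
        gene_compounds[g] = [single_plant_compound[p] for p in plants]
    for g in multi[core_size:]:
        # reject pairs whose combined plant coverage spans every plant, so
        # the planted core is exactly the all-plant intersection; with >= 3
        # plants no single compound spans all of them, hence feasible
        for _ in range(1000):
            picks = rng_assign.choice(spec.n_compounds, size=2, replace=False)
            cs = [compounds[int(j)] for j in sorted(picks)]
            if spec.n_plants < 3 or not _covers_all(cs):
                break
        else:
            raise FixtureError("could not place a multi-compound gene "
                               "without completing all-plant coverage")
        gene_compounds[g] = cs
    covered = {c for cs in gene_compounds.values() for c in cs}
    lonely = [c for c in compounds if c not in covered]
    if len(lonely) > len(singles):
        raise FixtureError(f"{len(lonely)} compounds would have no gene but "
                           f"only {len(singles)} single-target genes remain")
    for g, c in zip(singles, lonely):
        gene_compounds[g] = [c]
    rest = singles[len(lonely):]
    for g in rest:
        gene_compounds[g] = [compounds[int(rng_assign.integers(spec.n_compounds))]]

    rows = [Row(g, None, None) for g in orphans]
    for g, cs in gene_compounds.items():
        for c in cs:
            for p in compound_plants[c]:
                rows.append(Row(g, c, p))
    rows.sort(key=lambda r: (r.gene, r.compound or "", r.plant or ""))
    table = RelationshipTable(rows, provenance={"source": "synthetic",
                                                "seed": spec.seed})

    # planted enriched sets, concentrated at the top of the degree ranking
    degree = {g: len(set(cs)) for g, cs in gene_compounds.items()}
    degree.update({g: 0 for g in orphans})
    ranking = sorted(genes, key=lambda g: (-degree[g], g))
    rank_of = {g: i for i, g in enumerate(ranking)}
    planted: dict[str, tuple[str, ...]] = {}
    effect_ranks: dict[str, tuple[int, ...]] = {}
    top_stratum = list(multi)
    low_stratum = [g for g in genes if g not in set(multi)]
    for i, (size, conc) in enumerate(spec.planted_sets, start=1):
        if size > spec.n_genes:
            raise FixtureError(f"planted set size {size} exceeds gene count")
        n_top = min(round(size * conc), len(top_stratum))
        members = list(rng_gmt.choice(top_stratum, size=n_top, replace=False))
        pool = [g for g in low_stratum if g not in members]
        members += list(rng_gmt.choice(pool, size=size - n_top, replace=False))
        members = sorted(members)
        planted[f"PLANTED_{i}"] = tuple(members)
        effect_ranks[f"PLANTED_{i}"] = tuple(rank_of[g] for g in members)

    truth = FixtureTruth(
        orphan_genes=tuple(sorted(orphans)),
        cross_plant_compounds=tuple(sorted(
            c for c, ps in compound_plants.items() if len(ps) >= 2)),
        multi_compound_genes=tuple(sorted(multi)),
        common_core=tuple(sorted(core)),
        planted_set_members=planted,
        effect_ranks=effect_ranks,
    )
    if path is not None:
        write_relationship_csv(table, path)
    logger.info("generated fixture: %d genes (%d orphan, %d multi), "
                "%d compounds (%d cross-plant), %d plants, %d rows",
                spec.n_genes, n_orphan, n_multi, spec.n_compounds,
                len(truth.cross_plant_compounds), spec.n_plants, len(rows))
    return table, truth


def write_relationship_csv(table: RelationshipTable, path: str | Path) -> None:
    """Deterministic CSV emission (rows in stored order, LF newlines)."""
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["gene", "compound", "plant"])
        for r in table.rows:
            w.writerow([r.gene, r.compound or "", r.plant or ""])


def generate_gmt(universe: Sequence[str], n_sets: int,
                 planted: Optional[FixtureTruth] = None, seed: int = 0,
                 size_range: tuple[int, int] = (5, 40),
                 path: Optional[str | Path] = None,
                 database_label: str = "synthetic") -> GeneSetCollection:
    """A GMT collection: the truth's planted sets first (known positives),
    then ``n_sets`` background sets drawn uniformly from the universe."""
    universe = [g.upper() for g in universe]
    if not universe:
        raise FixtureError("empty universe")
    if size_range[1] > len(universe):
        raise FixtureError(f"set size {size_range[1]} exceeds universe "
                           f"({len(universe)})")
    rng = np.random.default_rng(seed)
    sets: dict[str, GeneSet] = {}
    if planted is not None:
        for name, members in planted.planted_set_members.items():
            sets[name] = GeneSet(name, "planted positive", tuple(members))
    for i in range(1, n_sets + 1):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = sorted(rng.choice(universe, size=size, replace=False))
        name = f"BG_{i:03d}"
        sets[name] = GeneSet(name, "background", tuple(members))
    coll = GeneSetCollection(sets, source=None, database_label=database_label)
    if path is not None:
        write_gmt(coll, path)
        coll.source = str(path)
    return coll


def generate_expression(genes: Sequence[str], n_samples: int,
                        planted: Optional[Sequence[tuple[Sequence[str], float]]] = None,
                        subgroup: Optional[Sequence[int]] = None,
                        seed: int = 0,
                        path: Optional[str | Path] = None) -> pd.DataFrame:
    """Gene x sample matrix: i.i.d. standard-normal baseline, with each
    planted (members, delta) set shifted by delta in the ``subgroup``
    sample columns.  A nonzero delta without a subgroup is an error."""
    if n_samples < 3:
        raise FixtureError("need >= 3 samples")
    genes = [g.upper() for g in genes]
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((len(genes), n_samples))
    df = pd.DataFrame(X, index=genes,
                      columns=[f"S{j + 1:02d}" for j in range(n_samples)])
    for members, delta in (planted or []):
        if delta != 0 and subgroup is None:
            raise FixtureError("planted shift requires an explicit subgroup")
        if delta != 0:
            rows = [g.upper() for g in members if g.upper() in df.index]
            df.loc[rows, df.columns[list(subgroup)]] += delta
    if path is not None:
        df.to_csv(path, sep="\t", lineterminator="\n")
    return df
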