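"""Enrichment engines: hypergeometric ORA, preranked GSEA, and GSVA.

All three methods are implemented from their statistical definitions.

* **ORA** tests whether a query gene list overlaps each gene set more than
  expected under hypergeometric sampling from a background universe.
* **Preranked GSEA** walks a ranked gene list accumulating a weighted
  Kolmogorov-Smirnov running sum; the enrichment score (ES) is the signed
  maximum deviation, normalized (NES) against a gene-tag permutation null.
* **GSVA** turns a gene x sample expression matrix into set x sample scores
  via Gaussian-kernel cumulative densities and a symmetric rank statistic.

Multiple-testing correction (Benjamini-Hochberg step-up / Bonferroni) is
delegated to statsmodels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .io_validation import RelationshipTable

logger = logging.getLogger("phytonet.enrichment")

_TINY = float(np.finfo(float).tiny)


class GMTParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    @property
    def member_set(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet]
    source: Optional[str] = None
    database_label: str = ""

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


def read_gmt(path: str | Path, database_label: str = "") -> GeneSetCollection:
    """Parse a tab-separated GMT file: name, description, member genes.

    Member symbols are uppercased; duplicate set names and lines with fewer
    than three fields are errors (with line numbers).
    """
    path = Path(path)
    sets: dict[str, GeneSet] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(),
                                  start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GMTParseError(f"{path}:{lineno}: expected >= 3 tab-separated "
                                f"fields, got {len(fields)}")
        name, desc = fields[0].strip(), fields[1].strip()
        if name in sets:
            raise GMTParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        members: list[str] = []
        seen: set[str] = set()
        for m in fields[2:]:
            m = m.strip().upper()
            if m and m not in seen:
                seen.add(m)
                members.append(m)
        if not members:
            raise GMTParseError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = GeneSet(name, desc, tuple(members))
    return GeneSetCollection(sets, source=str(path),
                             database_label=database_label or path.stem)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = ["\t".join((s.name, s.description) + s.members)
             for s in collection]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass
class EnrichmentRecord:
    set_name: str
    method: str                      # ORA | GSEA | GSVA
    p_raw: float
    p_adj: float
    overlap_k: Optional[int] = None  # ORA
    set_size: Optional[int] = None
    es: Optional[float] = None       # GSEA
    nes: Optional[float] = None
    direction: int = 1

    def as_row(self) -> dict:
        return {"set": self.set_name, "method": self.method,
                "k": self.overlap_k, "set_size": self.set_size,
                "ES": self.es, "NES": self.nes,
                "p_raw": self.p_raw, "p_adj": self.p_adj,
                "direction": self.direction}


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    cols = ["set", "method", "k", "set_size", "ES", "NES",
            "p_raw", "p_adj", "direction"]
    return pd.DataFrame([r.as_row() for r in records], columns=cols)


# ---------------------------------------------------------------------------
# multiple-testing correction

def adjust_pvalues(p: Sequence[float], method: str = "BH") -> list[float]:
    """Adjust p-values; ``BH`` step-up (monotone, capped at 1) or
    ``bonferroni``.  Input order is preserved."""
    p = list(p)
    if not p:
        return []
    if any(not (0 < x <= 1) for x in p):
        raise ValueError("p-values must lie in (0, 1]")
    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction {method!r}")
    return list(multipletests(p, method=key)[1])


# ---------------------------------------------------------------------------
# ORA

def ora_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric P(X >= k) of drawing k set members in a
    query of n from a background of N containing K set members."""
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return max(p, _TINY)


def ora(query: set[str], background: set[str],
        collection: GeneSetCollection, min_size: int = 3,
        correction: str = "BH") -> list[EnrichmentRecord]:
    """Hypergeometric over-representation analysis of ``query`` against every
    gene set, with sets restricted to the background and size-filtered
    (K < min_size excluded before testing).
    """
    query = {g.upper() for g in query}
    background = {g.upper() for g in background}
    if not query:
        raise ValueError("empty query")
    if not query <= background:
        raise ValueError("query must be a subset of the background; "
                         f"{len(query - background)} genes are outside it")
    N, n = len(background), len(query)
    tested: list[tuple[str, int, int, float]] = []
    for s in collection:
        inter_bg = s.member_set & background
        K = len(inter_bg)
        if K < min_size:
            continue
        k = len(inter_bg & query)
        tested.append((s.name, k, K, ora_pvalue(k, K, n, N)))
    if not tested:
        logger.warning("no gene set of size >= %d intersects the background",
                       min_size)
        return []
    adj = adjust_pvalues([t[3] for t in tested], method=correction)
    return [EnrichmentRecord(set_name=name, method="ORA", overlap_k=k,
                             set_size=K, p_raw=p, p_adj=pa)
            for (name, k, K, p), pa in zip(tested, adj)]


# ---------------------------------------------------------------------------
# preranked GSEA

def _walk_steps(weights: np.ndarray, hit_cols: np.ndarray,
                n_genes: int) -> np.ndarray:
    """Running-sum step matrix for one or many hit-index sets.

    ``hit_cols`` has shape (B, s): B member sets of equal size s given as
    positions in the ranking.  Hits step up proportionally to their weight
    (normalized over the set's total weight; uniform if all weights are 0),
    misses step down by 1/(N-s).
    """
    B, s = hit_cols.shape
    steps = np.full((B, n_genes), -1.0 / (n_genes - s))
    hw = weights[hit_cols]                        # (B, s)
    tot = hw.sum(axis=1, keepdims=True)
    vals = np.where(tot > 0, hw / np.where(tot > 0, tot, 1.0), 1.0 / s)
    steps[np.arange(B)[:, None], hit_cols] = vals
    return steps


def _signed_max_deviation(walk: np.ndarray) -> np.ndarray:
    """Per-row running-sum value of largest magnitude (the ES)."""
    ai = np.argmax(np.abs(walk), axis=1)
    return walk[np.arange(walk.shape[0]), ai]


def enrichment_score(scores: np.ndarray, hit_idx: Sequence[int],
                     weight: float = 1.0) -> float:
    """ES of one gene set: signed maximum deviation of the weighted
    Kolmogorov-Smirnov running sum over a descending ranking."""
    hit = np.asarray(sorted(hit_idx), dtype=int)[None, :]
    w = np.abs(np.asarray(scores, dtype=float)) ** weight
    walk = np.cumsum(_walk_steps(w, hit, len(scores)), axis=1)
    return float(_signed_max_deviation(walk)[0])


def _null_es(scores: np.ndarray, set_size: int, n_perm: int,
             weight: float, rng: np.random.Generator) -> np.ndarray:
    """Gene-tag permutation null: ES of ``n_perm`` random same-size sets."""
    N = len(scores)
    idx = np.argsort(rng.random((n_perm, N)), axis=1)[:, :set_size]
    w = np.abs(scores) ** weight
    walk = np.cumsum(_walk_steps(w, idx, N), axis=1)
    return _signed_max_deviation(walk)


def gsea_preranked(ranking: Sequence[tuple[str, float]],
                   collection: GeneSetCollection, weight: float = 1.0,
                   n_perm: int = 1000, min_size: int = 3,
                   seed: int = 0) -> list[EnrichmentRecord]:
    """Preranked GSEA with a gene-tag permutation null.

    ``ranking`` is a descending (gene, score) list with unique genes and
    finite scores.  For each retained set: ES as in
    :func:`enrichment_score`; p-value is the (+1)-corrected frequency of
    same-sign null ES at least as extreme (floored at 1/(n_perm+1));
    NES = ES / mean(|same-sign null ES|); FDR is estimated from the pooled
    signed null NES distribution across sets and reported as ``p_adj``.
    Relationship-table inputs carry no sample dimension, hence gene-tag
    (not phenotype) permutation.
    """
    genes = [g.upper() for g, _ in ranking]
    scores = np.asarray([s for _, s in ranking], dtype=float)
    if len(set(genes)) != len(genes):
        raise ValueError("ranking contains duplicate genes")
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    if np.any(np.diff(scores) > 0):
        raise ValueError("ranking must be sorted by descending score")
    pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)
    rng = np.random.default_rng(seed)

    results: list[dict] = []
    pooled_null_nes: list[np.ndarray] = []
    for s in collection:
        hit = sorted(pos[g] for g in s.member_set if g in pos)
        sz = len(hit)
        if sz < min_size or sz >= N:
            continue
        es = enrichment_score(scores, hit, weight)
        null = _null_es(scores, sz, n_perm, weight, rng)
        same = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same):
            p = (1 + np.sum(np.abs(same) >= abs(es))) / (1 + len(same))
            denom = float(np.mean(np.abs(same)))
        else:                      # no same-sign nulls: maximally extreme
            p = 1.0 / (1 + n_perm)
            denom = float(np.mean(np.abs(null))) or 1.0
        nes = es / denom if denom > 0 else 0.0
        # normalize the null the same way to build the pooled NES null
        pos_null, neg_null = null[null >= 0], null[null < 0]
        parts = []
        if len(pos_null):
            parts.append(pos_null / (np.mean(pos_null) or 1.0))
        if len(neg_null):
            parts.append(neg_null / (np.mean(np.abs(neg_null)) or 1.0))
        pooled_null_nes.append(np.concatenate(parts))
        results.append({"name": s.name, "k": sz, "es": es, "nes": nes,
                        "p": max(float(p), 1.0 / (1 + n_perm))})
    if not results:
        logger.warning("no gene set of size in [%d, %d) overlaps the ranking",
                       min_size, N)
        return []
    pool = np.concatenate(pooled_null_nes)
    obs_nes = np.asarray([r["nes"] for r in results])
    fdrs = []
    for r in results:
        nes = r["nes"]
        if nes >= 0:
            null_frac = np.mean(pool[pool >= 0] >= nes) if np.any(pool >= 0) else 0.0
            obs_frac = np.mean(obs_nes[obs_nes >= 0] >= nes)
        else:
            null_frac = np.mean(pool[pool < 0] <= nes) if np.any(pool < 0) else 0.0
            obs_frac = np.mean(obs_nes[obs_nes < 0] <= nes)
        q = null_frac / obs_frac if obs_frac > 0 else 1.0
        fdrs.append(min(1.0, max(q, _TINY)))
    return [EnrichmentRecord(set_name=r["name"], method="GSEA",
                             set_size=r["k"], es=r["es"], nes=r["nes"],
                             p_raw=r["p"], p_adj=q,
                             direction=1 if r["es"] >= 0 else -1)
            for r, q in zip(results, fdrs)]


# ---------------------------------------------------------------------------
# GSVA

def gaussian_kcdf(X: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel cumulative density across samples.

    z[i, j] = mean_k Phi((x[i,j] - x[i,k]) / h_i) with bandwidth
    h_i = sd_i / 4 (sample sd).  Zero-variance genes get a flat 0.5.
    Invariant under positive affine transforms of any single gene's values.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=1, ddof=1)
    Z = np.full_like(X, 0.5)
    ok = sd > 0
    if np.any(ok):
        h = (sd[ok] / 4.0)[:, None, None]
        diffs = (X[ok, :, None] - X[ok, None, :]) / h
        Z[ok] = sps.norm.cdf(diffs).mean(axis=2)
    return Z


def gsva(expr: pd.DataFrame, collection: GeneSetCollection,
         kernel: str = "gaussian", min_size: int = 15, max_size: int = 500,
         tau: float = 1.0) -> pd.DataFrame:
    """GSVA scores: set x sample matrix in [-1, 1].

    Pipeline: Gaussian-kernel CDF per gene -> per-sample gene ranking by
    decreasing density -> symmetric rank statistic |p/2 - r|^tau -> signed
    running-sum enrichment per set, scored as the maximum positive deviation
    minus the maximum negative deviation magnitude.  Sets whose intersection
    with the matrix falls outside [min_size, max_size] are excluded.
    """
    if kernel != "gaussian":
        raise ValueError("only the gaussian kernel is implemented")
    if expr.shape[1] < 3:
        raise ValueError("GSVA requires at least 3 samples")
    expr = expr.copy()
    expr.index = expr.index.str.upper()
    genes = list(expr.index)
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids in expression matrix")
    p, n = expr.shape
    Z = gaussian_kcdf(expr.values)

    # per-sample rank order, rank 1 = highest density; the symmetric rank
    # statistic depends only on the position, so it is one shared vector
    order = np.argsort(-Z, axis=0, kind="stable")          # (p, n)
    rank_stat = np.abs(p / 2.0 - np.arange(1, p + 1)) ** tau  # by position

    gene_pos = {g: i for i, g in enumerate(genes)}
    kept: list[tuple[str, np.ndarray]] = []
    for s in collection:
        idx = np.asarray(sorted(gene_pos[g] for g in s.member_set
                                if g in gene_pos), dtype=int)
        if min_size <= len(idx) <= max_size:
            kept.append((s.name, idx))
    if not kept:
        logger.warning("no gene set within size [%d, %d] maps onto the "
                       "expression matrix", min_size, max_size)
        return pd.DataFrame(columns=expr.columns)

    out = np.zeros((len(kept), n))
    for j in range(n):
        ordered_genes = order[:, j]
        inv = np.empty(p, dtype=int)
        inv[ordered_genes] = np.arange(p)   # gene row -> position in walk
        for si, (_, idx) in enumerate(kept):
            hit = np.zeros(p, dtype=bool)
            hit[inv[idx]] = True
            s_sz = len(idx)
            w = rank_stat[hit]
            steps = np.where(hit, 0.0, -1.0 / (p - s_sz))
            tot = w.sum()
            steps[hit] = (w / tot) if tot > 0 else 1.0 / s_sz
            walk = np.cumsum(steps)
            out[si, j] = max(walk.max(), 0.0) - max(-walk.min(), 0.0)
    return pd.DataFrame(out, index=[name for name, _ in kept],
                        columns=expr.columns)


# ---------------------------------------------------------------------------
# entity streams and shared-target set algebra

def compound_degree_ranking(table: RelationshipTable) -> list[tuple[str, float]]:
    """Network-mode gene ranking: score = number of distinct targeting
    compounds, ties broken lexicographically by gene symbol."""
    gc = table.gene_compounds()
    return sorted(((g, float(len(cs))) for g, cs in gc.items()),
                  key=lambda t: (-t[1], t[0]))


@dataclass
class EntityEnrichmentBundle:
    entity_id: str
    entity_type: str                 # compound | plant | global
    genes: tuple[str, ...]
    records: list[EnrichmentRecord] = field(default_factory=list)
    skipped: bool = False
    skip_reason: Optional[str] = None


def entity_enrichment(table: RelationshipTable,
                      collection: GeneSetCollection,
                      background: Optional[set[str]] = None,
                      method: str = "ORA", min_size: int = 3,
                      correction: str = "BH") -> list[EntityEnrichmentBundle]:
    """Per-compound, per-plant and global ORA streams.

    Each compound's query is its distinct target genes; each plant's query
    is the union of its compounds' targets; the global query is every gene
    in the table.  Every bundle is its own multiple-testing family.  An
    entity with an empty gene list is flagged skipped, never dropped.
    """
    if method != "ORA":
        raise NotImplementedError("entity streams support ORA; run GSEA/GSVA "
                                  "globally with an explicit ranking/matrix")
    if not table.rows:
        raise ValueError("empty table")
    if background is None:
        background = table.genes()

    def _bundle(eid: str, etype: str, genes: set[str]) -> EntityEnrichmentBundle:
        genes = genes & background
        b = EntityEnrichmentBundle(eid, etype, tuple(sorted(genes)))
        if not genes:
            b.skipped = True
            b.skip_reason = "no genes linked to this entity"
            return b
        b.records = ora(genes, background, collection,
                        min_size=min_size, correction=correction)
        return b

    bundles = [_bundle("global", "global", set(table.genes()))]
    cg = table.compound_genes()
    for c in sorted(cg):
        bundles.append(_bundle(c, "compound", cg[c]))
    pg = table.plant_genes()
    for pl in sorted(pg):
        bundles.append(_bundle(pl, "plant", pg[pl]))
    return bundles


@dataclass
class SharedTargets:
    per_plant: dict[str, frozenset[str]]
    unique: dict[str, frozenset[str]]
    core: frozenset[str]                       # targeted by every plant
    pairwise: dict[tuple[str, str], frozenset[str]]


def shared_target_analysis(table: RelationshipTable) -> SharedTargets:
    """Exact set algebra over plant -> target-gene mappings: per-plant unique
    targets, the common core hit by all plants, and pairwise overlaps."""
    pg = {p: frozenset(gs) for p, gs in table.plant_genes().items()}
    if len(pg) < 2:
        raise ValueError("shared-target analysis requires >= 2 plants")
    plants = sorted(pg)
    core = frozenset(set.intersection(*(set(pg[p]) for p in plants)))
    unique = {p: frozenset(pg[p] - set().union(*(pg[q] for q in plants
                                                 if q != p)))
              for p in plants}
    pairwise = {(a, b): pg[a] & pg[b]
                for i, a in enumerate(plants) for b in plants[i + 1:]}
    return SharedTargets(per_plant=pg, unique=unique, core=core,
                         pairwise=pairwise)
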