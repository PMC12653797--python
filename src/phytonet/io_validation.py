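"""Parsing, validation and cleaning of plant-compound-gene relationship tables.

A relationship table is a CSV with one relationship per row and up to three
columns: ``gene`` (mandatory), ``compound`` (optional), ``plant`` (optional).
Validation never mutates the data; cleaning is a separate pass, so both steps
can be logged independently for audit purposes.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

logger = logging.getLogger("phytonet.io")

RULE_VERSION = "1.0"

#: canonical column names, matched case-insensitively after whitespace stripping
_COLUMN_ALIASES = {
    "gene": "gene", "genes": "gene",
    "compound": "compound", "compounds": "compound",
    "plant": "plant", "plants": "plant", "herb": "plant", "herbs": "plant",
}

_WS = re.compile(r"\s+")
#: characters permitted in compound names after cleaning; preserves common
#: phytochemical punctuation (hyphens, parentheses, primes) while removing
#: control/format noise
_COMPOUND_DISALLOWED = re.compile(r"[^A-Za-z0-9 _()+'\-]")


class EmptyTableError(ValueError):
    """Raised when cleaning leaves no usable rows."""


@dataclass(frozen=True)
class ValidationRules:
    """Length and volume constraints applied during validation."""

    gene_len: tuple[int, int] = (2, 50)
    compound_len: tuple[int, int] = (3, 100)
    plant_len: tuple[int, int] = (1, 150)
    max_file_mb: float = 100.0
    max_invalid_fraction: float = 0.5
    max_relationships_per_entity: int = 1000

    def __post_init__(self) -> None:
        for lo, hi in (self.gene_len, self.compound_len, self.plant_len):
            if lo > hi or lo < 0:
                raise ValueError(f"empty or negative length range ({lo}, {hi})")
        if min(self.max_file_mb, self.max_invalid_fraction,
               self.max_relationships_per_entity) <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RawTable:
    """Rows exactly as read from disk; ``None`` marks an absent column."""

    rows: list[tuple[Optional[str], Optional[str], Optional[str]]]
    source_path: str
    byte_size: int
    has_gene: bool
    has_compound: bool
    has_plant: bool


@dataclass
class ValidationReport:
    status: str  # pass | warn | fail
    errors: list[tuple[int, str, str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    invalid_fraction: float = 0.0
    duplicate_count: int = 0
    n_rows: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n",
                              encoding="utf-8")

    def log(self) -> None:
        logger.info("validation status=%s rows=%d invalid_fraction=%.3f "
                    "duplicates=%d errors=%d warnings=%d", self.status,
                    self.n_rows, self.invalid_fraction, self.duplicate_count,
                    len(self.errors), len(self.warnings))
        for w in self.warnings:
            logger.warning("%s", w)


@dataclass(frozen=True)
class Row:
    gene: str
    compound: Optional[str]
    plant: Optional[str]


@dataclass
class RelationshipTable:
    """Cleaned relationships: genes uppercase, no duplicates, no absent genes."""

    rows: list[Row]
    provenance: dict = field(default_factory=dict)

    def genes(self) -> set[str]:
        return {r.gene for r in self.rows}

    def compounds(self) -> set[str]:
        return {r.compound for r in self.rows if r.compound is not None}

    def plants(self) -> set[str]:
        return {r.plant for r in self.rows if r.plant is not None}

    def gene_compounds(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {g: set() for g in self.genes()}
        for r in self.rows:
            if r.compound is not None:
                out[r.gene].add(r.compound)
        return out

    def compound_genes(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {c: set() for c in self.compounds()}
        for r in self.rows:
            if r.compound is not None:
                out[r.compound].add(r.gene)
        return out

    def compound_plants(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {c: set() for c in self.compounds()}
        for r in self.rows:
            if r.compound is not None and r.plant is not None:
                out[r.compound].add(r.plant)
        return out

    def plant_compounds(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {p: set() for p in self.plants()}
        for r in self.rows:
            if r.plant is not None and r.compound is not None:
                out[r.plant].add(r.compound)
        return out

    def plant_genes(self) -> dict[str, set[str]]:
        """Genes reached by each plant through its compounds."""
        cg = self.compound_genes()
        return {p: set().union(*(cg[c] for c in cs)) if cs else set()
                for p, cs in self.plant_compounds().items()}


@dataclass
class RelationshipStats:
    genes_per_compound_mean: Optional[float]
    cross_plant_compound_fraction: Optional[float]
    multi_compound_gene_fraction: Optional[float]
    orphan_gene_fraction: float
    chain_ratio: Optional[float]
    per_entity_relationship_counts: dict[str, int]
    over_threshold_entities: list[str] = field(default_factory=list)


def _detect_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",;\t").delimiter
    except csv.Error:
        return ","


def parse_relationship_csv(path: str | Path) -> RawTable:
    """Read a relationship CSV, auto-detecting the delimiter.

    Column headers are matched case-insensitively (and whitespace-stripped)
    to gene/compound/plant.  Row text is preserved verbatim; validation and
    cleaning are separate passes.
    """
    path = Path(path)
    byte_size = path.stat().st_size
    text = path.read_text(encoding="utf-8-sig")
    if not text.strip():
        return RawTable([], str(path), byte_size, False, False, False)
    delim = _detect_delimiter(text[:4096])
    reader = csv.reader(text.splitlines(), delimiter=delim)
    header = next(reader)
    colmap: dict[str, int] = {}
    for i, name in enumerate(header):
        canon = _COLUMN_ALIASES.get(name.strip().lower())
        if canon is not None and canon not in colmap:
            colmap[canon] = i
    rows = []
    for rec in reader:
        def cell(key: str) -> Optional[str]:
            i = colmap.get(key)
            if i is None or i >= len(rec):
                return None
            return rec[i]
        rows.append((cell("gene"), cell("compound"), cell("plant")))
    raw = RawTable(rows, str(path), byte_size,
                   "gene" in colmap, "compound" in colmap, "plant" in colmap)
    logger.info("parsed %s: %d rows, delimiter=%r, columns gene=%s "
                "compound=%s plant=%s", path, len(rows), delim,
                raw.has_gene, raw.has_compound, raw.has_plant)
    return raw


def _check_len(value: Optional[str], bounds: tuple[int, int]) -> bool:
    """True when the stripped value satisfies the inclusive length range."""
    v = value.strip()
    return bounds[0] <= len(v) <= bounds[1]


def validate(raw: RawTable, rules: ValidationRules = ValidationRules()) -> ValidationReport:
    """Check every row against the rules; never mutates the table.

    Status is ``fail`` only when gene data is structurally absent (no gene
    column or no rows); oversized files and >50% invalid rows downgrade the
    status to ``warn`` with detailed messages.
    """
    rep = ValidationReport(status="pass", n_rows=len(raw.rows))
    if not raw.has_gene or not raw.rows:
        rep.status = "fail"
        rep.errors.append((-1, "gene", "structure",
                           "no gene column or no data rows"))
        rep.invalid_fraction = 1.0
        return rep

    invalid_rows = 0
    entity_counts: Counter[str] = Counter()
    seen: Counter[tuple] = Counter()
    for i, (g, c, p) in enumerate(raw.rows):
        row_bad = False
        if g is None or not g.strip():
            rep.errors.append((i, "gene", "gene_missing", "gene value absent"))
            row_bad = True
        elif not _check_len(g, rules.gene_len):
            rep.errors.append((i, "gene", "gene_length",
                               f"gene {g.strip()!r} length outside "
                               f"{rules.gene_len}"))
            row_bad = True
        if c is not None and c.strip() and not _check_len(c, rules.compound_len):
            rep.errors.append((i, "compound", "compound_length",
                               f"compound length outside {rules.compound_len}"))
            row_bad = True
        if p is not None and p.strip() and not _check_len(p, rules.plant_len):
            rep.errors.append((i, "plant", "plant_length",
                               f"plant length outside {rules.plant_len}"))
            row_bad = True
        if row_bad:
            invalid_rows += 1
        for val in (g, c, p):
            if val is not None and val.strip():
                entity_counts[val.strip()] += 1
        seen[(g.strip() if g else None, c.strip() if c else None,
              p.strip() if p else None)] += 1

    rep.invalid_fraction = invalid_rows / len(raw.rows)
    rep.duplicate_count = sum(n - 1 for n in seen.values() if n > 1)
    if rep.duplicate_count:
        rep.warnings.append(f"{rep.duplicate_count} duplicate rows "
                            "(will be removed during cleaning)")
    for ent, n in sorted(entity_counts.items()):
        if n > rules.max_relationships_per_entity:
            rep.warnings.append(
                f"entity {ent!r} appears in {n} rows, exceeding the "
                f"{rules.max_relationships_per_entity}-relationship threshold")
    if raw.byte_size > rules.max_file_mb * 1024 * 1024:
        rep.warnings.append(f"file size {raw.byte_size} bytes exceeds "
                            f"{rules.max_file_mb} MB")
        rep.status = "warn"
    if rep.invalid_fraction > rules.max_invalid_fraction:
        rep.warnings.append(f"invalid fraction {rep.invalid_fraction:.2f} "
                            f"exceeds {rules.max_invalid_fraction}")
        rep.status = "warn"
    rep.log()
    return rep


def _clean_gene(g: Optional[str]) -> Optional[str]:
    if g is None:
        return None
    g = _WS.sub(" ", g.strip()).upper()
    return g or None


def _clean_compound(c: Optional[str]) -> Optional[str]:
    if c is None:
        return None
    c = _COMPOUND_DISALLOWED.sub("", c)
    c = _WS.sub(" ", c.strip())
    return c or None


def _clean_plant(p: Optional[str]) -> Optional[str]:
    if p is None:
        return None
    p = _WS.sub(" ", p.strip())
    return p or None


def clean(raw: RawTable) -> tuple[RelationshipTable, dict]:
    """Normalize whitespace, uppercase genes, strip disallowed compound
    characters, drop rows without a gene, and remove exact duplicates.

    Idempotent: cleaning an already-clean table is a no-op.
    """
    cleaned: list[Row] = []
    seen: set[tuple] = set()
    dropped_no_gene = 0
    duplicate_count = 0
    for g, c, p in raw.rows:
        gene = _clean_gene(g)
        if gene is None:
            dropped_no_gene += 1
            continue
        row = Row(gene, _clean_compound(c), _clean_plant(p))
        key = (row.gene, row.compound, row.plant)
        if key in seen:
            duplicate_count += 1
            continue
        seen.add(key)
        cleaned.append(row)
    if not cleaned:
        raise EmptyTableError("no usable rows after cleaning "
                              f"({dropped_no_gene} rows lacked a gene)")
    provenance = {
        "source_path": raw.source_path,
        "cleaned_at": datetime.now(timezone.utc).isoformat(),
        "rule_version": RULE_VERSION,
    }
    dup_report = {"duplicate_count": duplicate_count,
                  "dropped_no_gene": dropped_no_gene}
    logger.info("cleaned table: %d rows kept, %d duplicates removed, "
                "%d rows without gene dropped", len(cleaned),
                duplicate_count, dropped_no_gene)
    return RelationshipTable(cleaned, provenance), dup_report


def relationship_stats(table: RelationshipTable,
                       rules: ValidationRules = ValidationRules()) -> RelationshipStats:
    """Descriptive statistics of a cleaned table.

    Plant- or compound-dependent fractions are ``None`` when the relevant
    layer is entirely absent (distinct from a layer that exists but is
    sparse).  An orphan gene is one with no compound in any row.
    """
    if not table.rows:
        raise EmptyTableError("empty table")
    genes = table.genes()
    compounds = table.compounds()
    gc = table.gene_compounds()
    cg = table.compound_genes()
    cp = table.compound_plants()

    genes_per_compound = (
        sum(len(v) for v in cg.values()) / len(compounds) if compounds else None)
    cross_plant = (
        sum(1 for v in cp.values() if len(v) >= 2) / len(compounds)
        if compounds and table.plants() else None)
    multi_compound = (
        sum(1 for v in gc.values() if len(v) >= 2) / len(genes)
        if compounds else None)
    orphan = sum(1 for v in gc.values() if not v) / len(genes)

    chain_ratio: Optional[float] = None
    if table.plants():
        reachable = set().union(*table.plant_genes().values()) \
            if table.plant_genes() else set()
        chain_ratio = len(reachable & genes) / len(genes)

    counts: Counter[str] = Counter()
    for r in table.rows:
        for val in (r.gene, r.compound, r.plant):
            if val is not None:
                counts[val] += 1
    over = sorted(e for e, n in counts.items()
                  if n > rules.max_relationships_per_entity)
    return RelationshipStats(
        genes_per_compound_mean=genes_per_compound,
        cross_plant_compound_fraction=cross_plant,
        multi_compound_gene_fraction=multi_compound,
        orphan_gene_fraction=orphan,
        chain_ratio=chain_ratio,
        per_entity_relationship_counts=dict(counts),
        over_threshold_entities=over,
    )
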