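# Methods

This note records the statistical conventions, defaults and design choices
behind `phytonet`, at the level of detail a re-implementer would need.

## Data model and validation

A relationship table is a CSV with a mandatory `gene` column and optional
`compound` and `plant` columns, one association per row. Header matching is
case-insensitive after whitespace stripping; the delimiter is auto-detected
among comma, semicolon and tab. Validation and cleaning are deliberately
separate, side-effect-free passes so both can be audited:

- **Validation** records every rule violation with row and field. Length
  ranges (inclusive): genes 2–50 characters, compounds 3–100, plants 1–150.
  Files over 100 MB (on-disk bytes, measured before parsing) or with more
  than 50 % invalid rows downgrade the status to `warn`; more than 1000
  relationships on a single entity produces a per-entity warning. Only the
  structural absence of gene data (no gene column, no rows) is a `fail`.
- **Cleaning** collapses whitespace, uppercases genes, strips compound
  characters outside `[A-Za-z0-9 _()+'-]` (keeping the punctuation common
  in phytochemical names — hyphens, parentheses, primes — while removing
  control/format noise), drops rows without a gene, and removes exact
  (gene, compound, plant) duplicates. Cleaning is idempotent; absent
  optional values are a distinct `None`, never the empty string, so
  statistics can distinguish "no plant layer" from "blank plant".

Relationship statistics are computed over distinct entities: mean genes per
compound, fraction of compounds in ≥ 2 plants, fraction of genes hit by
≥ 2 compounds, orphan fraction (genes with no compound in any row), and a
*chain ratio* — the fraction of genes reachable from at least one plant via
a compound. The chain ratio is our interpretation of an otherwise undefined
"relationship chain" notion and is labelled as such.

## Network construction and topology

The graph is simple and undirected, with one node per distinct entity and
one edge per distinct co-occurring gene–compound or compound–plant pair
(edge weight 1 by default; optionally the supporting row count — weights
influence serialization only, never the topology statistics). Orphan genes
are retained as isolated nodes. A structural assertion runs on every build:
typed nodes, edges only between adjacent layers, matching layer tags, no
self-loops.

Conventions for centralities on possibly disconnected graphs:

- degree centrality `deg / (n−1)`;
- betweenness as the raw (unnormalized) shortest-path pair count;
- closeness with Wasserman–Faust scaling by the reachable fraction, so
  isolated nodes score 0 and values stay in [0, 1];
- eigenvector centrality by power iteration (tolerance 1e−6, ≤ 1000
  iterations) on the largest connected component, 0 elsewhere;
  non-convergence is a hard error naming the component.

A consequence of the strict layering worth stating plainly: a layered
tripartite simple graph contains **no triangles** (any triangle would need
a same-type or gene–plant edge), so its average clustering coefficient is
identically 0. The metric is still computed and reported; clustering-based
null comparisons on such graphs are degenerate by construction.

The community-size power-law diagnostic is the least-squares R² of
log(size) against log(rank) over descending community sizes — one fixed,
documented choice among several possible regressions.

## Communities and the configuration-model null

Community detection is seeded Louvain (networkx implementation) with a
resolution parameter (default 1.0); community labels are canonicalized by
smallest member so identical partitions always serialize identically.
Modularity is the unweighted Newman–Girvan form
`Q = Σ_c [e_c/m − (d_c/2m)²]`; an edgeless graph gets singleton communities
and Q = 0 by convention.

The null ensemble preserves each node's degree **and** the layered typing:
replicates are produced by double-edge swaps (10 × |E| attempted swaps per
replicate) applied separately within the gene–compound and compound–plant
layers, with proposals rejected if they would duplicate an existing edge.
Swapping the right-hand endpoints of two oriented within-layer edges cannot
create a same-type or gene–plant edge, so type safety holds by
construction. We chose swaps over stub matching because stub matching
produces multi-edges and self-loops that would have to be collapsed,
silently changing the degree sequence. This within-layer null is stricter
(lower-variance) than an untyped configuration model; results should be
read as "more structured than degree- and layer-matched random networks".
A layer with fewer than two edges cannot be rewired and is carried over
unchanged with a logged warning.

For the modularity null, every replicate is re-partitioned with seeded
Louvain before scoring, so the null distribution reflects the best
modularity achievable by a degree-matched random network — the appropriate
comparison for an optimized observed Q.

Empirical significance uses the (+1)-corrected tail frequency
`p = (1 + #{null ≥ observed}) / (1 + n_iter)` (upper tail by default for
modularity and clustering; `less` and `two-sided` available), which is
always in `[1/(n_iter+1), 1]`.

**Convergence monitoring.** Cumulative means of the null metric are
recorded at checkpoints 100, 200, …, n_iter. At checkpoint *t* the CV is
the population standard deviation of the cumulative means recorded at
checkpoints in (t/2, t], divided by |cumulative mean at t|. Early
checkpoints have one-element windows (CV 0); the statistic is meaningful
from checkpoint 300 on and the stability criterion (CV < 0.02 at every
checkpoint ≥ 500 of 1000) is evaluated on the late checkpoints only. On the
default synthetic network the observed maximum late-checkpoint CV is of
order 1e−4 — two orders of magnitude inside the bound — and the cumulative
mean at 1000 sits within 0.5 % of its value at 500.

## Enrichment engines

**ORA.** `p = P(X ≥ k)` under Hypergeometric(N, K, n) with N the background
size, K the set's intersection with the background, n the query size, k
the set–query overlap. Sets with K < 3 (default) are excluded *before*
testing. Correction is Benjamini–Hochberg step-up (default) or Bonferroni,
delegated to statsmodels; hypergeometric p-values are floored at the
smallest positive double.

**Preranked GSEA.** Input is a descending (gene, score) ranking with unique
genes. In network mode the score is the number of distinct targeting
compounds (ties broken lexicographically); any externally computed ranking
can be supplied instead. Hits increment the running sum by
`|score|^w / Σ_hits |score|^w` (w = 1 by default; uniform increments if all
hit weights are zero), misses decrement by `1/(N − |S|)`; ES is the signed
maximum deviation. The null permutes gene *tags*: `n_perm` (default 1000)
random same-size member sets. Phenotype permutation is impossible here —
relationship tables carry no sample dimension — and this deviation from
sample-permuting GSEA variants is deliberate and documented. The p-value is
the (+1)-corrected frequency of same-sign null ES at least as extreme;
comparing against same-sign nulls (rather than the full null) is what makes
the p-value uniform under a random ranking, which the test suite verifies
by a KS test. Its floor is `1/(n_same + 1) ≥ 1/(n_perm + 1)`.
`NES = ES / mean(|same-sign null ES|)`, so sign(NES) = sign(ES) always.
FDR follows the standard pooled-NES construction: the fraction of pooled
same-sign null NES at least as extreme, divided by the corresponding
fraction of observed NES, capped at 1.

**GSVA.** From a gene × sample matrix (≥ 3 samples): per-gene Gaussian
kernel cumulative densities `z_ij = mean_k Φ((x_ij − x_ik)/h_i)` with
bandwidth `h_i = sd_i/4` (sample sd); a zero-variance gene receives a flat
0.5. Per sample, genes are ranked by decreasing density and weighted by
the symmetric rank statistic `|p/2 − r|^τ` (τ = 1); the per-set running sum
(hit steps normalized by total hit weight, miss steps `1/(p − |S|)`) is
scored as the maximum positive deviation minus the maximum negative
deviation magnitude, giving scores in [−1, 1]. Set sizes are restricted to
15–500 after intersection. The bandwidth constant and the max-pos-minus-
max-neg scoring follow the method's original published definition. Scores
are invariant under positive affine transforms of any single gene and
equivariant under sample reordering; both properties are tested, as is
agreement to 1e−10 with an independently coded direct-formula oracle.

**Entity streams.** Enrichment runs globally, per compound (its distinct
targets) and per plant (union of its compounds' targets). Each stream is
its own multiple-testing family — matching the per-entity reporting this
kind of analysis requires — so p-values are *not* comparable across
entities. Entities with empty gene lists are flagged as skipped, never
silently dropped. Orphan genes participate only in the global stream.
Shared-target analysis is exact set algebra over plant → target mappings
(requires ≥ 2 plants): per-plant unique targets, pairwise overlaps, and
the core targeted by every plant.

## Synthetic fixtures

The generator emulates a small multi-herb screening dataset. Defaults (111
genes, 32 compounds, 3 plants; fractions 0.324 / 0.287 / 0.081) reproduce
the published structure of such a dataset; counts are placed exactly after
rounding (9 orphans, 32 multi-compound genes, 10 cross-plant compounds),
not merely in expectation, so downstream statistics are deterministic given
the seed. Ten genes (configurable) form a planted common core hit by one
single-plant compound per plant; rejection sampling guarantees no other
gene attains all-plant coverage when there are ≥ 3 plants (with 2 plants a
single cross-plant compound already spans all plants and exact core
recovery is not guaranteed). Planted GMT sets draw a configurable fraction
(default 0.8) of members from the multi-compound stratum, concentrating
them at the top of the degree ranking. One integer seed drives all
substreams via `SeedSequence` spawning; table, GMT and expression emissions
are byte-stable.

What the fixtures do **not** emulate: realistic compound chemistry, the
heavy-tailed degree distributions of literature-mined target tables
(fixture gene degrees are 0–3), correlated expression structure, or
database-derived gene-set overlap patterns. Passing tests therefore
demonstrate correctness of the statistics under controlled conditions, not
biological performance on real screening data. In particular the fixture
network is sparser than real curated tables of the same entity counts,
whose reported edge counts cannot be reconciled with their own sharing
fractions; we generate from the fractions, which are the well-defined
quantities.

## Numerical choices and degenerate inputs

- Permutation p-values floored at `1/(n_perm+1)`; hypergeometric at the
  machine tiny; GSEA FDR capped into (0, 1].
- Eigenvector centrality: power iteration, tol 1e−6, max 1000 iterations.
- All-equal GSEA scores → uniform hit increments (valid, tested).
- Louvain ties broken by the seeded node shuffle; labels canonicalized.
- Empty-edge graphs: Q = 0 with singleton communities; `null_test`
  requires ≥ 10 iterations; density requires ≥ 2 nodes.
- Composition percentages are rounded to 1 d.p. and may sum to 99.9/100.1.

## Problem sizes used in the test suite

The suite exercises each stochastic property at sizes chosen to make the
statistical assertions sharp while keeping the suite fast: the ORA sweep
enumerates every configuration up to N = 12; GSEA calibration uses 200
sets × 200 permutations and recovery uses 100 seeded runs at 200 genes;
the null-model integrity check covers 100 replicates on each of 20 random
graphs; the convergence criterion runs the full 1000-replicate null on the
default 146-node fixture network, as does `scripts/acceptance.py`.

## Known limitations

- The within-layer null is stricter than an untyped configuration model;
  empirical p-values may be conservative relative to ensembles that mix
  layers.
- Gene-tag permutation GSEA ignores inter-gene correlation; on expression-
  derived rankings a sample-permutation null would be preferable when
  samples exist.
- No gene-symbol alias mapping, chemical-structure normalization or
  species handling: inputs are taken at face value after cleaning.
- GSVA requires an expression matrix; it is skipped (with a recorded
  reason) in relationship-table-only runs.
- Directed relationship semantics, STRING-style interaction expansion and
  leading-edge reporting are out of scope.
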