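# phytonet

Tripartite **plant–compound–gene** network analysis for network pharmacology.

Multi-herb preparations act through many bioactive compounds hitting many
gene targets at once. Understanding such formulations requires keeping the
three-tier hierarchy intact: which plant contributes which compounds, which
compounds share targets, and which genes are reached by every plant.
`phytonet` ingests a simple relationship table (one `gene, compound, plant`
row per known association), validates and cleans it, builds a typed
tripartite network, tests its structure against a degree-preserving null
model, and runs three complementary gene-set enrichment engines — all from
a single command, with reproducible, hierarchically organized outputs.

It is aimed at natural-product and traditional-medicine researchers who
have curated compound–target tables but no bioinformatics pipeline, and at
methodologists who want transparent, oracle-tested implementations of the
underlying statistics.

## What it computes

**Network layer.** Nodes are typed (`gene` / `compound` / `plant`); edges
exist only between adjacent layers (gene–compound, compound–plant). The
package reports density `2m / n(n−1)`, degree / betweenness / closeness /
eigenvector centralities, hub compounds (degree ≥ 5 by default), and
Louvain communities with Newman–Girvan modularity

```
Q = Σ_c [ e_c/m − (d_c / 2m)² ]
```

Observed structure is compared against a **configuration-model null**: 1000
replicates generated by double-edge swaps constrained within each layer, so
every replicate preserves the exact degree sequence *and* the tripartite
typing. Significance is the (+1)-corrected empirical tail probability, and
a cumulative-mean convergence trajectory (coefficient of variation at
checkpoints 100, 200, …) documents that 1000 replicates suffice.

**Enrichment layer.** Three engines, implemented from their statistical
definitions:

- **ORA** — upper-tail hypergeometric test `P(X ≥ k)` of a query gene list
  against each GMT set, Benjamini–Hochberg (or Bonferroni) corrected,
  minimum set size 3.
- **Preranked GSEA** — weighted Kolmogorov–Smirnov running sum over a
  descending gene ranking (network mode ranks genes by the number of
  distinct targeting compounds); ES is the signed maximum deviation, the
  null is 1000 gene-tag permutations, `NES = ES / mean |same-sign null ES|`,
  FDR from the pooled signed null NES distribution.
- **GSVA** — Gaussian-kernel cumulative densities per gene (bandwidth
  sd/4), per-sample symmetric rank statistic `|p/2 − r|`, and a running-sum
  score in [−1, 1] per set and sample; requires an explicit gene × sample
  expression matrix.

Enrichment runs as parallel streams: globally, per compound (its targets),
and per plant (union of its compounds' targets), each as its own
multiple-testing family, plus exact shared-target set algebra across
plants.

**Synthetic fixtures.** A first-class generator emits relationship tables
with exact entity counts and sharing fractions (defaults: 111 genes, 32
compounds, 3 plants; 32.4 % cross-plant compounds, 28.7 % multi-compound
genes, 8.1 % orphan genes), GMT collections with planted positives, and
expression matrices with planted group shifts — all byte-reproducible from
one seed, with machine-readable ground truth.

## Worked example

```python
import numpy as np
from phytonet import (FixtureSpec, generate_relationships, generate_gmt,
                      relationship_stats, build_network, topology_summary,
                      louvain_partition, null_test, ora,
                      shared_target_analysis)

table, truth = generate_relationships(FixtureSpec(seed=11))
stats = relationship_stats(table)
net = build_network(table)
topo = topology_summary(net)
part = louvain_partition(net, seed=3)
ens = null_test(net, "modularity", n_iter=1000, seed=5)
```

prints (via the accompanying report calls):

```
genes=111 compounds=32 plants=3
orphan fraction      0.081
multi-compound genes 0.288
cross-plant cmpds    0.312
network: 146 nodes, 186 edges, density 0.0176
composition: {'gene': 76.0, 'compound': 21.9, 'plant': 2.1}
modularity Q = 0.6730
null Q = 0.6135 +/- 0.0072, empirical p = 0.000999
max CV beyond checkpoint 500: 4.86e-04
top ORA hit: PLANTED_1 k=16/20 p_adj=3.72e-06
genes targeted by all plants: 10
```

Reading: the generated table reproduces the requested sharing/orphan
fractions exactly (up to 1/n rounding); the observed modularity (0.673)
exceeds all 1000 degree-matched random networks (p = 1/1001), so the
community structure is not a by-product of the degree sequence; the
cumulative null mean is stable to 3 decimal places long before 1000
replicates; the planted gene set is recovered as the top ORA hit; and the
10-gene common core planted across all three plants is recovered exactly
by the shared-target analysis.

### Command line

```bash
phytonet run relationships.csv --gmt kegg.gmt --gmt gobp.gmt \
    --out results/ --seed 7
```

populates `1_network/` (GEXF + node-link JSON graphs, topology and null
statistics), `2_figures/visualization/` (300 DPI PNGs), `3_gene_selection/`
(degree-ranked genes, per-entity gene lists, shared targets) and
`4_enrichment/` (per-entity CSV tables), plus `report.md` and a
`manifest.json` with input/output digests and all seeds. A YAML file with
the same keys as `phytonet.config.RunConfig` may replace the CSV argument;
unknown keys are rejected outright.

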