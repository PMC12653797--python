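"""GMT parsing, ORA, multiple-testing correction, entity streams and
shared-target set algebra."""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phytonet.enrichment import (EntityEnrichmentBundle, GMTParseError,
                                 GeneSet, GeneSetCollection, adjust_pvalues,
                                 compound_degree_ranking, entity_enrichment,
                                 ora, ora_pvalue, read_gmt,
                                 shared_target_analysis, write_gmt)
from conftest import make_table


def coll(*sets):
    return GeneSetCollection({s.name: s for s in sets})


# ------------------------------------------------------------------------ GMT

def test_read_gmt_basic(tmp_path):
    p = tmp_path / "s.gmt"
    p.write_text("S1\tdesc\tTNF\tIL6\nS2\tother\takt1\ttnf\tEGFR\n")
    c = read_gmt(p)
    assert c.sets["S1"].members == ("TNF", "IL6")
    assert c.sets["S2"].members == ("AKT1", "TNF", "EGFR")   # uppercased


def test_read_gmt_short_line_names_line_number(tmp_path):
    p = tmp_path / "bad.gmt"
    p.write_text("S1\tdesc\tTNF\nS2\tonlydesc\n")
    with pytest.raises(GMTParseError, match=":2:"):
        read_gmt(p)


def test_read_gmt_duplicate_name(tmp_path):
    p = tmp_path / "dup.gmt"
    p.write_text("S1\td\tTNF\nS1\td\tIL6\n")
    with pytest.raises(GMTParseError, match="duplicate"):
        read_gmt(p)


def test_gmt_round_trip(tmp_path):
    c = coll(GeneSet("A", "d1", ("TNF", "IL6")),
             GeneSet("B", "d2", ("EGFR",)))
    write_gmt(c, tmp_path / "o.gmt")
    back = read_gmt(tmp_path / "o.gmt")
    assert {s.name: s.members for s in back} == \
        {s.name: s.members for s in c}


# ------------------------------------------------------------------------ ORA

def _ora_enumeration(k, K, N, n):
    """Exhaustive oracle: fraction of n-subsets of [N] with >= k members
    among the first K elements."""
    total = hits = 0
    for combo in combinations(range(N), n):
        total += 1
        if sum(1 for x in combo if x < K) >= k:
            hits += 1
    return Fraction(hits, total)


def test_ora_worked_example_66_of_252():
    genes = [f"G{i}" for i in range(10)]
    background = set(genes)
    query = set(genes[:3]) | {genes[8], genes[9]}       # n=5, k=3
    s = GeneSet("S", "", tuple(genes[:4]))              # K=4
    recs = ora(query, background, coll(s))
    assert recs[0].overlap_k == 3
    assert recs[0].p_raw == pytest.approx(66 / 252)


def test_ora_zero_overlap_gives_p_one():
    genes = [f"G{i}" for i in range(8)]
    s = GeneSet("S", "", tuple(genes[:3]))
    recs = ora(set(genes[5:]), set(genes), coll(s))
    assert recs[0].overlap_k == 0
    assert recs[0].p_raw == pytest.approx(1.0)


def test_ora_min_size_excludes_small_sets():
    genes = [f"G{i}" for i in range(10)]
    small = GeneSet("SMALL", "", tuple(genes[:2]))
    big = GeneSet("BIG", "", tuple(genes[:5]))
    recs = ora(set(genes[:4]), set(genes), coll(small, big), min_size=3)
    assert [r.set_name for r in recs] == ["BIG"]


def test_ora_query_must_be_subset():
    with pytest.raises(ValueError):
        ora({"X"}, {"A", "B"}, coll(GeneSet("S", "", ("A", "B", "C"))))


def test_ora_empty_after_filtering_warns(caplog):
    recs = ora({"A"}, {"A", "B"}, coll(GeneSet("S", "", ("Z1", "Z2", "Z3"))))
    assert recs == []


def test_ora_pvalue_matches_enumeration_small_sweep():
    """Exhaustive check for every configuration with N <= 8 (the full
    N <= 12 sweep runs in the acceptance suite)."""
    for N in range(1, 9):
        for n in range(1, N + 1):
            for K in range(0, N + 1):
                for k in range(0, min(K, n) + 1):
                    expect = float(_ora_enumeration(k, K, N, n))
                    assert ora_pvalue(k, K, n, N) == pytest.approx(
                        expect, abs=1e-12), (N, K, n, k)


# ---------------------------------------------------------------- adjustment

def test_bh_step_up_worked_example():
    assert adjust_pvalues([0.005, 0.01, 0.03, 0.04]) == \
        pytest.approx([0.02, 0.02, 0.04, 0.04])


def test_single_p_unchanged_both_methods():
    assert adjust_pvalues([0.03]) == pytest.approx([0.03])
    assert adjust_pvalues([0.03], "bonferroni") == pytest.approx([0.03])


def test_bonferroni_multiplies_and_caps():
    assert adjust_pvalues([0.01, 0.5, 0.9], "bonferroni") == \
        pytest.approx([0.03, 1.0, 1.0])


def test_adjust_empty_and_invalid():
    assert adjust_pvalues([]) == []
    with pytest.raises(ValueError):
        adjust_pvalues([0.0, 0.5])
    with pytest.raises(ValueError):
        adjust_pvalues([0.5], "holm")


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(min_value=1e-8, max_value=1.0), min_size=1,
                max_size=20))
def test_bh_properties(ps):
    adj = adjust_pvalues(ps)
    # adjusted >= raw, capped at 1
    assert all(a >= p - 1e-12 and a <= 1.0 for a, p in zip(adj, ps))
    # monotone in the sorted order
    order = np.argsort(ps)
    sorted_adj = [adj[i] for i in order]
    assert all(a <= b + 1e-12 for a, b in zip(sorted_adj, sorted_adj[1:]))
    # invariant to permutation up to re-indexing
    perm = list(reversed(range(len(ps))))
    adj_perm = adjust_pvalues([ps[i] for i in perm])
    assert np.allclose([adj_perm[perm.index(i)] for i in range(len(ps))], adj)


# ------------------------------------------------------------- entity streams

ROWS = [("G1", "C1", "P1"), ("G2", "C1", "P1"), ("G3", "C2", "P1"),
        ("G3", "C3", "P2"), ("G4", "C3", "P2"), ("ORPHAN", None, None)]


def _collection_for_rows():
    return coll(GeneSet("S", "", ("G1", "G2", "G3", "G4", "ORPHAN")))


def test_plant_bundle_is_union_of_compound_targets():
    bundles = entity_enrichment(make_table(ROWS), _collection_for_rows())
    by_id = {(b.entity_type, b.entity_id): b for b in bundles}
    assert by_id[("plant", "P1")].genes == ("G1", "G2", "G3")
    assert by_id[("plant", "P2")].genes == ("G3", "G4")


def test_orphan_gene_only_in_global_bundle():
    bundles = entity_enrichment(make_table(ROWS), _collection_for_rows())
    for b in bundles:
        if b.entity_type == "global":
            assert "ORPHAN" in b.genes
        else:
            assert "ORPHAN" not in b.genes


def test_shared_compound_genes_in_both_plants():
    rows = ROWS + [("G5", "C4", "P1"), ("G5", "C4", "P2")]
    bundles = entity_enrichment(make_table(rows), _collection_for_rows())
    by_id = {(b.entity_type, b.entity_id): b for b in bundles}
    assert "G5" in by_id[("plant", "P1")].genes
    assert "G5" in by_id[("plant", "P2")].genes


def test_each_bundle_is_its_own_testing_family():
    bundles = entity_enrichment(make_table(ROWS), _collection_for_rows())
    for b in bundles:
        if not b.skipped and b.records:
            # a single tested set: BH leaves its p unchanged
            assert b.records[0].p_adj == pytest.approx(b.records[0].p_raw)


# ------------------------------------------------------------- shared targets

def test_shared_target_worked_example():
    rows = []
    targets = {"P1": ["A", "B", "C"], "P2": ["B", "C", "D"], "P3": ["C", "E"]}
    for i, (p, genes) in enumerate(targets.items()):
        for g in genes:
            rows.append((g, f"C{i}", p))
    sh = shared_target_analysis(make_table(rows))
    assert sh.core == {"C"}
    assert sh.unique["P1"] == {"A"}
    assert sh.pairwise[("P1", "P2")] == {"B", "C"}


def test_disjoint_plants_have_empty_core():
    rows = [("A", "C1", "P1"), ("B", "C2", "P2")]
    sh = shared_target_analysis(make_table(rows))
    assert sh.core == frozenset()
    assert sh.unique["P1"] == {"A"}
    assert sh.unique["P2"] == {"B"}


def test_single_plant_rejected():
    with pytest.raises(ValueError, match="2 plants"):
        shared_target_analysis(make_table([("A", "C1", "P1")]))


def test_fixture_common_core_recovered(default_table, default_truth):
    sh = shared_target_analysis(default_table)
    assert sh.core == frozenset(default_truth.common_core)


# ------------------------------------------------------------------- ranking

def test_compound_degree_ranking_ties_lexicographic():
    rows = [("B", "C1", None), ("B", "C2", None),
            ("A", "C1", None), ("A", "C3", None), ("Z", "C1", None)]
    ranking = compound_degree_ranking(make_table(rows))
    assert ranking == [("A", 2.0), ("B", 2.0), ("Z", 1.0)]
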