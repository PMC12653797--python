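import numpy as np
import pytest

from phytonet import build_network
from phytonet.fixtures import FixtureSpec, generate_relationships
from phytonet.io_validation import RawTable, RelationshipTable, Row


@pytest.fixture(scope="session")
def default_fixture():
    """Default synthetic dataset: 111 genes, 32 compounds, 3 plants."""
    return generate_relationships(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def default_table(default_fixture):
    return default_fixture[0]


@pytest.fixture(scope="session")
def default_truth(default_fixture):
    return default_fixture[1]


@pytest.fixture(scope="session")
def default_network(default_table):
    return build_network(default_table)


def make_raw(rows, has_gene=True, has_compound=True, has_plant=True,
             byte_size=100):
    """RawTable from (gene, compound, plant) string triples."""
    return RawTable(list(rows), source_path="<memory>", byte_size=byte_size,
                    has_gene=has_gene, has_compound=has_compound,
                    has_plant=has_plant)


def make_table(rows):
    """Cleaned RelationshipTable from (gene, compound, plant) triples,
    where None marks an absent value."""
    return RelationshipTable([Row(g, c, p) for g, c, p in rows])


def random_tripartite_graph(rng, n_genes=8, n_compounds=4, n_plants=2,
                            p_gc=0.4, p_cp=0.6):
    """Random typed layered graph built through the table constructor."""
    rows = []
    genes = [f"G{i}" for i in range(n_genes)]
    compounds = [f"C{i}" for i in range(n_compounds)]
    plants = [f"P{i}" for i in range(n_plants)]
    for g in genes:
        for c in compounds:
            if rng.random() < p_gc:
                rows.append((g, c, None))
    for c in compounds:
        for p in plants:
            if rng.random() < p_cp:
                # attach through an arbitrary gene row so the pair exists
                rows.append((genes[int(rng.integers(n_genes))], c, p))
    if not rows:
        rows.append((genes[0], compounds[0], plants[0]))
    return build_network(make_table(rows))
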