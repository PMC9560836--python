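import pytest

from benzentropy import MolecularGraph, fixture_graphs


@pytest.fixture(scope="session")
def oracle_fixtures():
    """100+ seeded small graphs for brute-force oracle checks."""
    return fixture_graphs(seed=20220, n=120)


@pytest.fixture
def benzene():
    """C6 ring."""
    return MolecularGraph.from_edges((i, (i + 1) % 6) for i in range(6))


def brute_force_line_graph(g: MolecularGraph) -> MolecularGraph:
    """O(m^2) all-pairs shared-endpoint line graph — the independent oracle
    for MolecularGraph.line_graph."""
    from itertools import combinations

    edges = []
    for e, f in combinations(g.edges, 2):
        if set(e) & set(f):
            edges.append((e, f))
    return MolecularGraph.from_edges(edges, isolated=g.edges)
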