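import numpy as np
import pytest

from torsionlink.graph import BipartiteGraph, build_graph
from torsionlink.io import AssociationTable


@pytest.fixture
def tiny_table() -> AssociationTable:
    """Star plus a pendant: c1-d1, c1-d2, c1-d3, c2-d1."""
    return AssociationTable(
        records=(
            ("c1", "d1", 1),
            ("c1", "d2", 1),
            ("c1", "d3", 1),
            ("c2", "d1", 1),
            ("c2", "d3", 0),
        )
    )


@pytest.fixture
def tiny_graph(tiny_table) -> BipartiteGraph:
    return build_graph(tiny_table)


@pytest.fixture
def single_edge_graph() -> BipartiteGraph:
    return build_graph(AssociationTable(records=(("c1", "d1", 1),)))


def random_bipartite(rng: np.random.Generator, n: int, m: int, p: float) -> BipartiteGraph:
    """Random bipartite graph with at least one edge."""
    while True:
        A = (rng.random((n, m)) < p).astype(np.int8)
        if A.sum() > 0:
            return BipartiteGraph(
                tuple(f"c{i}" for i in range(n)), tuple(f"d{j}" for j in range(m)), A
            )
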