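import numpy as np
import pytest

from torsionlink.graph import EdgeSubgraph, build_graph, edge_subgraph
from torsionlink.io import AssociationTable
from torsionlink.simplicial import (
    _log_torsion_of_subgraph,
    boundary_matrix,
    build_complex,
    hodge_laplacian,
    log_torsion,
    pseudo_determinant,
    torsion_weights,
)

from _oracles import count_spanning_trees
from conftest import random_bipartite


def _sub(nodes, edges, center=None) -> EdgeSubgraph:
    nodes = frozenset(nodes)
    return EdgeSubgraph(
        center=tuple(center) if center else (min(nodes),),
        nodes=nodes,
        edges=frozenset(tuple(sorted(e)) for e in edges),
        order=1,
    )


def _random_connected_sub(rng, max_nodes=8):
    """Random connected graph (not necessarily bipartite) as an EdgeSubgraph."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        p = rng.uniform(0.3, 0.9)
        edges = [(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p]
        seen = {0}
        frontier = [0]
        adj = {v: set() for v in range(n)}
        for u, v in edges:
            adj[u].add(v)
            adj[v].add(u)
        while frontier:
            x = frontier.pop()
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    frontier.append(y)
        if len(seen) == n and edges:
            return _sub(range(n), edges)


def test_build_complex_single_edge():
    cx = build_complex(_sub({0, 1}, [(0, 1)]), Q=1)
    assert cx.simplices_by_dim == (((0,), (1,)), ((0, 1),))


def test_build_complex_bipartite_has_no_triangles(tiny_graph):
    sub = edge_subgraph(tiny_graph, 0, tiny_graph.global_index("d1"), P=2)
    cx = build_complex(sub, Q=2)
    assert cx.dim == 1  # no odd cycles, so no 2-simplices


def test_build_complex_triangle():
    cx = build_complex(_sub({0, 1, 2}, [(0, 1), (0, 2), (1, 2)]), Q=2)
    assert [len(level) for level in cx.simplices_by_dim] == [3, 3, 1]


def test_boundary_matrix_edge_signs():
    cx = build_complex(_sub({0, 1}, [(0, 1)]), Q=1)
    assert boundary_matrix(cx, 1).tolist() == [[-1], [1]]


def test_boundary_matrix_triangle_signs_and_dd_zero():
    cx = build_complex(_sub({0, 1, 2}, [(0, 1), (0, 2), (1, 2)]), Q=2)
    B1, B2 = boundary_matrix(cx, 1), boundary_matrix(cx, 2)
    # edges ordered (0,1), (0,2), (1,2); triangle column = (+1, -1, +1)
    assert B2.ravel().tolist() == [1, -1, 1]
    assert np.all(B1 @ B2 == 0)


def test_boundary_matrix_out_of_range():
    cx = build_complex(_sub({0, 1}, [(0, 1)]), Q=1)
    with pytest.raises(ValueError):
        boundary_matrix(cx, 2)


def test_hodge_laplacian_single_edge():
    cx = build_complex(_sub({0, 1}, [(0, 1)]), Q=1)
    assert hodge_laplacian(cx, 0).tolist() == [[1, -1], [-1, 1]]
    assert hodge_laplacian(cx, 1).tolist() == [[2]]


def test_hodge_laplacian_path3():
    cx = build_complex(_sub({0, 1, 2}, [(0, 1), (1, 2)]), Q=1)
    Z1 = hodge_laplacian(cx, 1)
    assert np.allclose(np.diag(Z1), 2)
    assert abs(Z1[0, 1]) == 1


def test_pseudo_determinant_examples():
    assert pseudo_determinant(np.diag([0.0, 2.0, 3.0])) == pytest.approx(6.0)
    assert pseudo_determinant(np.zeros((3, 3))) == pytest.approx(1.0)
    cx = build_complex(_sub({0, 1}, [(0, 1)]), Q=1)
    assert pseudo_determinant(hodge_laplacian(cx, 0)) == pytest.approx(2.0)


def test_pseudo_determinant_rejects_indefinite():
    with pytest.raises(FloatingPointError):
        pseudo_determinant(np.diag([-1.0, 2.0]))


@pytest.mark.parametrize(
    "edges,expected",
    [
        ([(0, 1)], 0.5 * np.log(2)),  # single edge
        ([(0, 1), (1, 2)], 0.5 * np.log(3)),  # path of 3: pdet = n * tau = 3
        ([(0, 1), (1, 2), (2, 3), (0, 3)], 0.5 * np.log(16)),  # 4-cycle: 4 * 4
    ],
)
def test_log_torsion_closed_forms(edges, expected):
    nodes = {v for e in edges for v in e}
    cx = build_complex(_sub(nodes, edges), Q=1)
    assert log_torsion(cx, 1) == pytest.approx(expected, abs=1e-12)


def test_log_torsion_edgeless_is_zero():
    cx = build_complex(_sub({5}, []), Q=1)
    assert log_torsion(cx, 1) == 0.0


@pytest.mark.parametrize("seed", range(10))
def test_matrix_tree_oracle(seed):
    """pdet(Z1) = n * (#spanning trees) for connected graphs, any Q=1 complex."""
    rng = np.random.default_rng(seed)
    sub = _random_connected_sub(rng)
    cx = build_complex(sub, Q=1)
    n = len(sub.nodes)
    tau = count_spanning_trees(sorted(sub.nodes), sorted(sub.edges))
    assert pseudo_determinant(hodge_laplacian(cx, 1)) == pytest.approx(n * tau, rel=1e-6)


@pytest.mark.parametrize("seed", range(6))
def test_log_torsion_permutation_invariant(seed):
    rng = np.random.default_rng(100 + seed)
    sub = _random_connected_sub(rng)
    base = log_torsion(build_complex(sub, Q=2), 2)
    nodes = sorted(sub.nodes)
    for _ in range(10):
        perm = dict(zip(nodes, rng.permutation(nodes)))
        relabeled = _sub(
            [perm[v] for v in nodes], [(perm[u], perm[v]) for u, v in sub.edges]
        )
        assert log_torsion(build_complex(relabeled, Q=2), 2) == pytest.approx(base, abs=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_spectral_agreement_b1(seed):
    """Non-zero eigenvalues of B1^T B1 match those of B1 B1^T."""
    rng = np.random.default_rng(200 + seed)
    sub = _random_connected_sub(rng)
    cx = build_complex(sub, Q=1)
    B1 = boundary_matrix(cx, 1).astype(float)
    up = np.linalg.eigvalsh(B1.T @ B1)
    down = np.linalg.eigvalsh(B1 @ B1.T)
    up, down = up[up > 1e-8], down[down > 1e-8]
    assert np.allclose(np.sort(up), np.sort(down), atol=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_fast_route_matches_full_complex(seed):
    rng = np.random.default_rng(300 + seed)
    g = random_bipartite(rng, 5, 5, 0.4)
    u, v = g.edges()[0]
    sub = edge_subgraph(g, u, v, P=2)
    assert _log_torsion_of_subgraph(sub, 1) == pytest.approx(
        log_torsion(build_complex(sub, 1), 1), abs=1e-9
    )


def test_torsion_weights_single_edge(single_edge_graph):
    cache = torsion_weights(single_edge_graph, P=1, Q=1)
    half_ln2 = 0.5 * np.log(2)
    assert cache.edge(0, 1) == pytest.approx(half_ln2, abs=1e-12)
    # both endpoints' node subgraphs contain the edge, so the self weight is the same
    assert cache.node(0) == pytest.approx(half_ln2)
    assert cache.node(1) == pytest.approx(half_ln2)


def test_torsion_weights_structurally_identical_edges():
    # two disjoint single edges: identical local structure, identical weights
    table = AssociationTable(records=(("c1", "d1", 1), ("c2", "d2", 1)))
    g = build_graph(table)
    cache = torsion_weights(g, P=1, Q=1)
    values = list(cache.edge_weights.values())
    assert values[0] == pytest.approx(values[1], abs=1e-12)


def test_torsion_weights_disabled_all_one(tiny_graph):
    cache = torsion_weights(tiny_graph, P=1, Q=1, enabled=False)
    assert all(w == 1.0 for w in cache.edge_weights.values())
    assert all(w == 1.0 for w in cache.node_weights.values())


def test_torsion_q2_inert_on_bipartite(tiny_graph):
    c1 = torsion_weights(tiny_graph, P=1, Q=1)
    c2 = torsion_weights(tiny_graph, P=1, Q=2)
    for k in c1.edge_weights:
        assert c1.edge_weights[k] == pytest.approx(c2.edge_weights[k], abs=1e-12)


def test_complex_face_closure_validated():
    from torsionlink.simplicial import SimplicialComplex

    with pytest.raises(ValueError, match="closed under faces"):
        SimplicialComplex(simplices_by_dim=(((0,), (1,)), ((0, 2),)))
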