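"""Oriented clique complexes, Hodge Laplacians and analytic torsion.

The analytic torsion of a simplicial complex S is a spectral invariant built
from the pseudo-determinants |Z_g| (product of non-zero eigenvalues) of its
Hodge Laplacians Z_g = B_g^T B_g + B_{g+1} B_{g+1}^T, where B_g is the signed
boundary matrix between g-simplices and their (g-1)-faces.  For the complexes
used here the closed forms are

    Q = 1:  T(S) = |Z_1|^{1/2}
    Q = 2:  T(S) = |Z_1|^{1/2} |Z_2|

and the quantity consumed by message propagation is log T(S).

Simplices are stored as strictly ascending tuples of global node indices;
boundary signs follow the alternating (-1)^j convention over ordered vertex
deletions.  Analytic torsion is invariant under the orientation convention, so
any consistent choice works (verified by permutation-invariance tests).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import BipartiteGraph, EdgeSubgraph, edge_subgraph, node_subgraph

__all__ = [
    "SimplicialComplex",
    "TorsionCache",
    "build_complex",
    "boundary_matrix",
    "hodge_laplacian",
    "pseudo_determinant",
    "log_torsion",
    "torsion_weights",
]

# eigenvalues below ZERO_TOL * max(1, lambda_max) count as zero modes
ZERO_TOL = 1e-8


@dataclass(frozen=True)
class SimplicialComplex:
    """Simplices grouped by dimension; closed under taking faces."""

    simplices_by_dim: tuple[tuple[tuple[int, ...], ...], ...]

    def __post_init__(self) -> None:
        for g, simplices in enumerate(self.simplices_by_dim):
            seen = set()
            for s in simplices:
                if len(s) != g + 1:
                    raise ValueError(f"{s} is not a {g}-simplex")
                if list(s) != sorted(set(s)):
                    raise ValueError(f"simplex {s} is not strictly ascending")
                if s in seen:
                    raise ValueError(f"duplicate simplex {s}")
                seen.add(s)
        # face closure
        for g in range(1, len(self.simplices_by_dim)):
            faces = set(self.simplices_by_dim[g - 1])
            for s in self.simplices_by_dim[g]:
                for j in range(len(s)):
                    if s[:j] + s[j + 1 :] not in faces:
                        raise ValueError(f"complex not closed under faces at {s}")

    @property
    def dim(self) -> int:
        return len(self.simplices_by_dim) - 1

    def n_simplices(self, g: int) -> int:
        if 0 <= g <= self.dim:
            return len(self.simplices_by_dim[g])
        return 0


@dataclass(frozen=True)
class TorsionCache:
    """Per-edge and per-node log-torsion values used as propagation weights."""

    edge_weights: dict[tuple[int, int], float]
    node_weights: dict[int, float]

    def edge(self, u: int, v: int) -> float:
        return self.edge_weights[(u, v) if u < v else (v, u)]

    def node(self, a: int) -> float:
        return self.node_weights[a]


def build_complex(sub: EdgeSubgraph, Q: int) -> SimplicialComplex:
    """Clique complex of a subgraph up to dimension Q.

    0-simplices are the nodes, 1-simplices the edges, 2-simplices the 3-cliques
    (only for Q = 2; a purely bipartite subgraph has none).
    """
    if Q not in (1, 2):
        raise ValueError("complex dimension Q must be 1 or 2")
    nodes = tuple((v,) for v in sorted(sub.nodes))
    edges = tuple(sorted(sub.edges))
    levels: list[tuple[tuple[int, ...], ...]] = [nodes, edges]
    if Q == 2:
        adj: dict[int, set[int]] = {v: set() for v in sub.nodes}
        for u, v in sub.edges:
            adj[u].add(v)
            adj[v].add(u)
        triangles = []
        for u, v in edges:
            for w in sorted(adj[u] & adj[v]):
                if w > v:
                    triangles.append((u, v, w))
        levels.append(tuple(sorted(triangles)))
    # drop empty top levels so .dim reflects the simplices actually present
    while len(levels) > 1 and not levels[-1]:
        levels.pop()
    return SimplicialComplex(simplices_by_dim=tuple(levels))


def boundary_matrix(cx: SimplicialComplex, g: int) -> np.ndarray:
    """Signed boundary matrix B_g, shape (#(g-1)-simplices, #g-simplices).

    The column of simplex (v0 < ... < vg) carries (-1)^j in the row of the face
    obtained by deleting vj, so B_{g-1} B_g = 0 exactly.
    """
    if not (1 <= g <= cx.dim):
        raise ValueError(f"boundary dimension {g} out of range for complex of dim {cx.dim}")
    rows = {s: i for i, s in enumerate(cx.simplices_by_dim[g - 1])}
    cols = cx.simplices_by_dim[g]
    B = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for c, simplex in enumerate(cols):
        for j in range(len(simplex)):
            face = simplex[:j] + simplex[j + 1 :]
            B[rows[face], c] = (-1) ** j
    return B


def hodge_laplacian(cx: SimplicialComplex, g: int) -> np.ndarray:
    """Hodge Laplacian Z_g = B_g^T B_g + B_{g+1} B_{g+1}^T over g-simplices."""
    if not (0 <= g <= cx.dim):
        raise ValueError(f"dimension {g} out of range for complex of dim {cx.dim}")
    n = cx.n_simplices(g)
    Z = np.zeros((n, n), dtype=float)
    if g >= 1:
        B = boundary_matrix(cx, g)
        Z += B.T @ B
    if g + 1 <= cx.dim and cx.n_simplices(g + 1) > 0:
        B_up = boundary_matrix(cx, g + 1)
        Z += B_up @ B_up.T
    return Z


def _log_pseudo_det(Z: np.ndarray, tol: float = ZERO_TOL) -> float:
    """log of the product of non-zero eigenvalues; 0 (empty product) if all zero."""
    if Z.size == 0:
        return 0.0
    eigvals = np.linalg.eigvalsh((Z + Z.T) / 2.0)
    lam_max = float(eigvals[-1]) if eigvals.size else 0.0
    cut = tol * max(1.0, lam_max)
    if eigvals[0] < -cut:
        raise FloatingPointError(f"significantly negative eigenvalue {eigvals[0]:.3e}")
    nonzero = eigvals[eigvals > cut]
    return float(np.sum(np.log(nonzero))) if nonzero.size else 0.0


def pseudo_determinant(Z: np.ndarray, tol: float = ZERO_TOL) -> float:
    """Product of eigenvalues above tol * max(1, lambda_max); 1 if all are zero."""
    return float(np.exp(_log_pseudo_det(np.asarray(Z, dtype=float), tol)))


def log_torsion(cx: SimplicialComplex, Q: int) -> float:
    """log analytic torsion of a complex, via the closed forms.

    Q = 1 gives (1/2) log|Z_1|; Q = 2 adds log|Z_2|.  A complex with no edges
    (an isolated node) contributes a neutral log-torsion of 0.
    """
    if Q not in (1, 2):
        raise ValueError("Q must be 1 or 2")
    if cx.n_simplices(1) == 0:
        return 0.0
    value = 0.5 * _log_pseudo_det(hodge_laplacian(cx, 1))
    if Q == 2 and cx.dim >= 2 and cx.n_simplices(2) > 0:
        value += _log_pseudo_det(hodge_laplacian(cx, 2))
    return value


def _log_torsion_via_graph_laplacian(sub: EdgeSubgraph) -> float:
    """Fast route for triangle-free complexes.

    When no 2-simplices exist, Z_1 = B_1^T B_1 shares its non-zero spectrum with
    Z_0 = B_1 B_1^T, the ordinary graph Laplacian over the subgraph's nodes,
    which is usually the much smaller matrix.
    """
    nodes = sorted(sub.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    L = np.zeros((n, n), dtype=float)
    for u, v in sub.edges:
        i, j = index[u], index[v]
        L[i, i] += 1.0
        L[j, j] += 1.0
        L[i, j] -= 1.0
        L[j, i] -= 1.0
    return 0.5 * _log_pseudo_det(L)


def _subgraph_has_triangle(sub: EdgeSubgraph) -> bool:
    adj: dict[int, set[int]] = {v: set() for v in sub.nodes}
    for u, v in sub.edges:
        adj[u].add(v)
        adj[v].add(u)
    return any(adj[u] & adj[v] for u, v in sub.edges)


def _log_torsion_of_subgraph(sub: EdgeSubgraph, Q: int) -> float:
    if not sub.edges:
        return 0.0
    if Q == 1 or not _subgraph_has_triangle(sub):
        return _log_torsion_via_graph_laplacian(sub)
    return log_torsion(build_complex(sub, Q), Q)


def torsion_weights(
    graph: BipartiteGraph, P: int = 1, Q: int = 1, enabled: bool = True
) -> TorsionCache:
    """Log-torsion of the edge-centred subgraph of every edge, and of every
    node-centred subgraph (the self-loop weight).

    With ``enabled=False`` (the ablation arm) every weight is 1, which reduces
    propagation to the standard unweighted scheme.
    """
    edge_weights: dict[tuple[int, int], float] = {}
    node_weights: dict[int, float] = {}
    if not enabled:
        for u, v in graph.edges():
            edge_weights[(u, v)] = 1.0
        for a in range(graph.n_nodes):
            node_weights[a] = 1.0
        return TorsionCache(edge_weights, node_weights)
    for u, v in graph.edges():
        sub = edge_subgraph(graph, u, v, P)
        edge_weights[(u, v)] = _log_torsion_of_subgraph(sub, Q)
    for a in range(graph.n_nodes):
        sub = node_subgraph(graph, a, P)
        node_weights[a] = _log_torsion_of_subgraph(sub, Q)
    return TorsionCache(edge_weights, node_weights)


def write_torsion_tsv(graph: BipartiteGraph, cache: TorsionCache, path) -> None:
    """Dump per-edge log-torsion as ``circ_id <TAB> drug_id <TAB> log_torsion``."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("circ_id\tdrug_id\tlog_torsion\n")
        for (u, v), w in sorted(cache.edge_weights.items()):
            fh.write(f"{graph.node_id(u)}\t{graph.node_id(v)}\t{w:.12g}\n")
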