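"""Bipartite circRNA-drug graph and P-hop subgraph extraction.

Nodes carry a global index: circRNAs occupy ``0 .. N-1`` in first-appearance
order, drugs ``N .. N+M-1``.  Only circRNA-drug edges exist; similarity
information never becomes a propagation edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AssociationTable

__all__ = ["BipartiteGraph", "EdgeSubgraph", "build_graph", "degrees", "edge_subgraph", "node_subgraph"]


@dataclass
class BipartiteGraph:
    circ_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]
    A: np.ndarray  # (N, M) binary biadjacency

    _adj: list[set[int]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A)
        n, m = len(self.circ_ids), len(self.drug_ids)
        if self.A.shape != (n, m):
            raise ValueError(f"adjacency shape {self.A.shape} does not match ({n}, {m})")
        if not np.isin(self.A, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if len(set(self.circ_ids)) != n or len(set(self.drug_ids)) != m:
            raise ValueError("node id lists must be duplicate-free")
        adj: list[set[int]] = [set() for _ in range(n + m)]
        for i, j in zip(*np.nonzero(self.A)):
            adj[int(i)].add(n + int(j))
            adj[n + int(j)].add(int(i))
        self._adj = adj

    @property
    def n_circ(self) -> int:
        return len(self.circ_ids)

    @property
    def n_drug(self) -> int:
        return len(self.drug_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_circ + self.n_drug

    def is_circ(self, idx: int) -> bool:
        return idx < self.n_circ

    def node_id(self, idx: int) -> str:
        if idx < self.n_circ:
            return self.circ_ids[idx]
        return self.drug_ids[idx - self.n_circ]

    def circ_index(self, circ_id: str) -> int:
        self._ensure_lookups()
        return self._circ_lookup[circ_id]

    def drug_index(self, drug_id: str) -> int:
        self._ensure_lookups()
        return self._drug_lookup[drug_id]

    def _ensure_lookups(self) -> None:
        if not hasattr(self, "_drug_lookup"):
            self._circ_lookup = {c: i for i, c in enumerate(self.circ_ids)}
            self._drug_lookup = {d: self.n_circ + j for j, d in enumerate(self.drug_ids)}

    def global_index(self, node_id: str) -> int:
        """Global index for a circRNA or drug id (circRNAs win on a clash)."""
        self._ensure_lookups()
        if node_id in self._circ_lookup:
            return self._circ_lookup[node_id]
        if node_id in self._drug_lookup:
            return self._drug_lookup[node_id]
        raise KeyError(f"unknown node id {node_id!r}")

    def neighbors(self, idx: int) -> frozenset[int]:
        return frozenset(self._adj[idx])

    def edges(self) -> list[tuple[int, int]]:
        """All edges as ascending (circ_idx, drug_global_idx) pairs."""
        n = self.n_circ
        return [(int(i), n + int(j)) for i, j in zip(*np.nonzero(self.A))]


@dataclass(frozen=True)
class EdgeSubgraph:
    """A local subgraph around an edge (or single node), used to build complexes."""

    center: tuple[int, ...]
    nodes: frozenset[int]
    edges: frozenset[tuple[int, int]]
    order: int

    def __post_init__(self) -> None:
        if not set(self.center) <= self.nodes:
            raise ValueError("center nodes must be contained in the node set")
        for u, v in self.edges:
            if u >= v:
                raise ValueError("subgraph edges must be stored ascending")
            if u not in self.nodes or v not in self.nodes:
                raise ValueError("edge endpoint outside node set")


def build_graph(table: AssociationTable) -> BipartiteGraph:
    """Build the bipartite graph from an association table.

    Edges come from label-1 records only; ids from label-0 records are retained
    as (possibly isolated) nodes.  Node order is first appearance.
    """
    if len(table) == 0:
        raise ValueError("cannot build a graph from an empty association table")
    circ_ids: list[str] = []
    drug_ids: list[str] = []
    circ_seen: dict[str, int] = {}
    drug_seen: dict[str, int] = {}
    for circ, drug, _ in table.records:
        if circ not in circ_seen:
            circ_seen[circ] = len(circ_ids)
            circ_ids.append(circ)
        if drug not in drug_seen:
            drug_seen[drug] = len(drug_ids)
            drug_ids.append(drug)
    A = np.zeros((len(circ_ids), len(drug_ids)), dtype=np.int8)
    n_pos = 0
    for circ, drug, label in table.records:
        if label == 1:
            A[circ_seen[circ], drug_seen[drug]] = 1
            n_pos += 1
    if n_pos == 0:
        raise ValueError("association table has no positive (label-1) records")
    return BipartiteGraph(tuple(circ_ids), tuple(drug_ids), A)


def degrees(graph: BipartiteGraph) -> np.ndarray:
    """Node degrees under the self-loop convention: bipartite degree + 1.

    The +1 keeps the self-term of the propagation rule well defined (isolated
    nodes get degree 1), mirroring renormalised graph convolution.
    """
    return np.array([len(graph._adj[i]) + 1 for i in range(graph.n_nodes)], dtype=float)


def _bfs_ball(graph: BipartiteGraph, seeds: set[int], hops: int) -> set[int]:
    visited = set(seeds)
    frontier = set(seeds)
    for _ in range(hops):
        nxt: set[int] = set()
        for node in frontier:
            nxt |= graph._adj[node]
        nxt -= visited
        if not nxt:
            break
        visited |= nxt
        frontier = nxt
    return visited


def _induced_edges(graph: BipartiteGraph, nodes: set[int]) -> frozenset[tuple[int, int]]:
    edges = set()
    for u in nodes:
        for v in graph._adj[u]:
            if v in nodes and u < v:
                edges.add((u, v))
    return frozenset(edges)


def edge_subgraph(graph: BipartiteGraph, u: int, v: int, P: int) -> EdgeSubgraph:
    """Edge-centred subgraph: nodes within P hops of u or v, with induced edges."""
    if P < 1:
        raise ValueError("subgraph order P must be >= 1")
    if graph.is_circ(u) == graph.is_circ(v):
        raise ValueError("edge subgraph centre must span a circRNA and a drug")
    nodes = _bfs_ball(graph, {u, v}, P)
    return EdgeSubgraph(center=(u, v), nodes=frozenset(nodes), edges=_induced_edges(graph, nodes), order=P)


def node_subgraph(graph: BipartiteGraph, a: int, P: int) -> EdgeSubgraph:
    """Node-centred subgraph: a plus its <=P-hop neighbourhood, with induced edges."""
    if P < 1:
        raise ValueError("subgraph order P must be >= 1")
    if not (0 <= a < graph.n_nodes):
        raise ValueError(f"node index {a} out of range")
    nodes = _bfs_ball(graph, {a}, P)
    return EdgeSubgraph(center=(a,), nodes=frozenset(nodes), edges=_induced_edges(graph, nodes), order=P)
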