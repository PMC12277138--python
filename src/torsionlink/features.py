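"""Initial node representations: position, one-hot, random, and similarity features.

Feature matrices are (N + M) x d, row-aligned with the global node index of the
graph they were built from.  Similarity matrices are symmetric with unit
diagonal and entries in [0, 1].
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd

from .graph import BipartiteGraph
from .io import SequenceSet, SmilesTable

__all__ = [
    "position_features",
    "onehot_features",
    "random_features",
    "kmer_features",
    "gip_kernel",
    "structural_similarity",
    "sequence_similarity",
    "fuse_similarity",
    "sim_features",
]


def position_features(graph: BipartiteGraph) -> np.ndarray:
    """Adjacency-row features: node i gets row i of the symmetric (N+M)^2 adjacency."""
    n, m = graph.n_circ, graph.n_drug
    H = np.zeros((n + m, n + m), dtype=float)
    H[:n, n:] = graph.A
    H[n:, :n] = graph.A.T
    return H


def onehot_features(graph: BipartiteGraph) -> np.ndarray:
    """Identity features: a unique indicator per node."""
    return np.eye(graph.n_nodes, dtype=float)


def random_features(graph: BipartiteGraph, dist: str, d: int, seed: int) -> np.ndarray:
    """i.i.d. random features, uniform on [0, 1) or standard normal."""
    if d < 1:
        raise ValueError("feature dimension must be >= 1")
    rng = np.random.default_rng(seed)
    if dist == "uniform":
        return rng.random((graph.n_nodes, d))
    if dist == "normal":
        return rng.standard_normal((graph.n_nodes, d))
    raise ValueError(f"dist must be 'uniform' or 'normal', got {dist!r}")


def kmer_features(seqs: SequenceSet, k: int) -> pd.DataFrame:
    """Circular k-mer frequencies, one row per circRNA.

    circRNAs are covalently closed, so counting wraps around the sequence end:
    a sequence of length L contributes exactly L k-mer occurrences and every row
    sums to 1.  Columns are the 4^k DNA k-mers in lexicographic order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    alphabet = "ACGT"
    kmers = ["".join(p) for p in product(alphabet, repeat=k)]
    col = {km: i for i, km in enumerate(kmers)}
    rows = np.zeros((len(seqs.entries), 4**k), dtype=float)
    ids = list(seqs.entries)
    for r, cid in enumerate(ids):
        seq = seqs.entries[cid]
        if len(seq) < k:
            raise ValueError(f"sequence {cid!r} shorter than k={k}")
        wrapped = seq + seq[: k - 1]
        for i in range(len(seq)):
            kmer = wrapped[i : i + k]
            if "N" in kmer:
                continue  # ambiguous positions carry no count
            rows[r, col[kmer]] += 1.0
        total = rows[r].sum()
        if total == 0:
            raise ValueError(f"sequence {cid!r} has no unambiguous k-mers")
        rows[r] /= len(seq)
    return pd.DataFrame(rows, index=ids, columns=kmers)


def gip_kernel(A: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Gaussian interaction profile kernel over the rows or columns of A.

    K(i, j) = exp(-gamma ||x_i - x_j||^2) with the bandwidth normalised by the
    mean squared profile norm, gamma = 1 / mean_i ||x_i||^2 (gamma = 1 when all
    profiles are zero).
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("interaction matrix must be non-empty")
    X = A if axis == "rows" else A.T if axis == "cols" else None
    if X is None:
        raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")
    sq_norms = (X**2).sum(axis=1)
    mean_norm = sq_norms.mean()
    gamma = 1.0 / mean_norm if mean_norm > 0 else 1.0
    d2 = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return K


def structural_similarity(smiles: SmilesTable) -> np.ndarray:
    """Tanimoto similarity of Morgan fingerprints (radius 2, 2048 bits).

    Rows/columns follow the insertion order of the SMILES table; an unparsable
    SMILES raises with the offending drug id.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator
    from rdkit.DataStructs import TanimotoSimilarity

    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    fps = []
    for did, smi in smiles.entries.items():
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES for drug {did!r}: {smi!r}")
        fps.append(gen.GetFingerprint(mol))
    n = len(fps)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = TanimotoSimilarity(fps[i], fps[j])
    return S


def sequence_similarity(feats: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Cosine similarity between k-mer frequency rows, clipped to [0, 1].

    Zero-norm rows get similarity 0 to every other row; the diagonal is 1.
    """
    X = np.asarray(feats, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    C = (X @ X.T) / np.outer(safe, safe)
    C[norms == 0, :] = 0.0
    C[:, norms == 0] = 0.0
    np.clip(C, 0.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    return C


def fuse_similarity(S1: np.ndarray | None, S2: np.ndarray) -> np.ndarray:
    """Elementwise mean of two similarity matrices; S2 alone when S1 is missing."""
    if S1 is None:
        return np.asarray(S2, dtype=float)
    S1, S2 = np.asarray(S1, dtype=float), np.asarray(S2, dtype=float)
    if S1.shape != S2.shape:
        raise ValueError(f"similarity shapes differ: {S1.shape} vs {S2.shape}")
    return 0.5 * (S1 + S2)


def sim_features(Sc: np.ndarray, Sd: np.ndarray) -> np.ndarray:
    """Block layout: circRNA rows carry (Sc | 0), drug rows carry (0 | Sd)."""
    Sc, Sd = np.asarray(Sc, dtype=float), np.asarray(Sd, dtype=float)
    n, m = Sc.shape[0], Sd.shape[0]
    if Sc.shape != (n, n) or Sd.shape != (m, m):
        raise ValueError("similarity matrices must be square")
    H = np.zeros((n + m, n + m), dtype=float)
    H[:n, :n] = Sc
    H[n:, n:] = Sd
    return H
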