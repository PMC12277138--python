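"""Negative sampling, cross-validation, evaluation and candidate ranking.

The protocol is leakage-free: each fold's graph, torsion cache and
adjacency-derived features are rebuilt from the training positives only, so no
held-out edge (positive or negative) influences training.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from .estimator import TorsionGNNClassifier
from .graph import BipartiteGraph
from .io import AssociationTable, RunConfig, SequenceSet, SmilesTable

__all__ = [
    "FoldSplit",
    "Metrics",
    "sample_negatives",
    "kfold_split",
    "evaluate",
    "train_fold",
    "cross_validate",
    "rank_candidates",
]

Pair = tuple[str, str]


@dataclass(frozen=True)
class FoldSplit:
    fold_id: int
    train_pos: tuple[Pair, ...]
    train_neg: tuple[Pair, ...]
    test_pos: tuple[Pair, ...]
    test_neg: tuple[Pair, ...]


@dataclass(frozen=True)
class Metrics:
    auc: float
    aupr: float
    f1: float
    accuracy: float
    recall: float
    precision: float

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def sample_negatives(graph: BipartiteGraph, n: int, seed: int) -> list[Pair]:
    """Uniformly sample n distinct unobserved (zero-entry) pairs, without replacement."""
    zeros = np.argwhere(np.asarray(graph.A) == 0)
    if n > len(zeros):
        raise ValueError(f"cannot sample {n} negatives from {len(zeros)} unobserved pairs")
    rng = np.random.default_rng(seed)
    chosen = zeros[rng.choice(len(zeros), size=n, replace=False)]
    return [(graph.circ_ids[i], graph.drug_ids[j]) for i, j in chosen]


def kfold_split(pos: list[Pair], neg: list[Pair], k: int, seed: int) -> list[FoldSplit]:
    """Shuffle positives and negatives independently and partition into k folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(pos) < k or len(neg) < k:
        raise ValueError(f"need at least k={k} positives and negatives")
    rng = np.random.default_rng(seed)
    pos_perm = [pos[i] for i in rng.permutation(len(pos))]
    neg_perm = [neg[i] for i in rng.permutation(len(neg))]
    pos_chunks = np.array_split(np.arange(len(pos)), k)
    neg_chunks = np.array_split(np.arange(len(neg)), k)
    folds = []
    for f in range(k):
        test_p = {int(i) for i in pos_chunks[f]}
        test_n = {int(i) for i in neg_chunks[f]}
        folds.append(
            FoldSplit(
                fold_id=f,
                train_pos=tuple(p for i, p in enumerate(pos_perm) if i not in test_p),
                train_neg=tuple(p for i, p in enumerate(neg_perm) if i not in test_n),
                test_pos=tuple(p for i, p in enumerate(pos_perm) if i in test_p),
                test_neg=tuple(p for i, p in enumerate(neg_perm) if i in test_n),
            )
        )
    return folds


def evaluate(scores, labels, threshold: float = 0.5) -> Metrics:
    """Ranking and threshold metrics for one evaluation set.

    AUC uses the rank statistic with tie correction, AUPR the step-wise
    precision-recall integration (average precision); accuracy, recall,
    precision and F1 are computed at the 0.5 threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise ValueError("evaluation needs at least one positive and one negative label")
    pred = (scores >= threshold).astype(int)
    return Metrics(
        auc=float(roc_auc_score(labels, scores)),
        aupr=float(average_precision_score(labels, scores)),
        f1=float(f1_score(labels, pred, zero_division=0)),
        accuracy=float(accuracy_score(labels, pred)),
        recall=float(recall_score(labels, pred, zero_division=0)),
        precision=float(precision_score(labels, pred, zero_division=0)),
    )


def _node_universe(table: AssociationTable) -> tuple[tuple[str, ...], tuple[str, ...]]:
    circ = tuple(dict.fromkeys(c for c, _, _ in table.records))
    drug = tuple(dict.fromkeys(d for _, d, _ in table.records))
    return circ, drug


def _estimator_from_config(config: RunConfig, seed: int) -> TorsionGNNClassifier:
    return TorsionGNNClassifier(
        encoder=config.encoder,
        layers=config.layers,
        hidden_dim=config.hidden_dim,
        out_dim=config.out_dim,
        feature_init=config.feature_init,
        subgraph_order=config.subgraph_order,
        complex_dim=config.complex_dim,
        torsion_enabled=config.torsion_enabled,
        lr=config.lr,
        epochs=config.epochs,
        kmer_k=config.kmer_k,
        random_state=seed,
    )


def train_fold(
    split: FoldSplit,
    table: AssociationTable,
    config: RunConfig,
    sequences: SequenceSet | None = None,
    smiles: SmilesTable | None = None,
) -> tuple[TorsionGNNClassifier, Metrics]:
    """Train on one fold's training pairs and evaluate on its held-out pairs.

    The node universe comes from the full table so held-out nodes keep an
    embedding, but the graph (hence torsion cache and adjacency features) is
    built from training positives only.
    """
    if not split.train_pos:
        raise ValueError("fold has no positive training edges")
    X_train = list(split.train_pos) + list(split.train_neg)
    y_train = np.array([1] * len(split.train_pos) + [0] * len(split.train_neg))
    est = _estimator_from_config(config, seed=config.seed + split.fold_id)
    est.fit(
        X_train,
        y_train,
        nodes=_node_universe(table),
        sequences=sequences,
        smiles=smiles,
    )
    X_test = list(split.test_pos) + list(split.test_neg)
    y_test = np.array([1] * len(split.test_pos) + [0] * len(split.test_neg))
    metrics = evaluate(est.predict_proba(X_test)[:, 1], y_test)
    return est, metrics


def cross_validate(
    table: AssociationTable,
    config: RunConfig,
    sequences: SequenceSet | None = None,
    smiles: SmilesTable | None = None,
    negatives: list[Pair] | None = None,
) -> dict:
    """Balanced-negative k-fold cross-validation; returns per-fold and summary metrics.

    Negatives are sampled once per run (not per fold or epoch) from unobserved
    pairs of the full graph, matched in count to the positives, unless an
    explicit list is supplied.
    """
    from .graph import build_graph

    pos = table.positives()
    if negatives is None:
        graph_full = build_graph(table)
        negatives = sample_negatives(graph_full, len(pos), seed=config.seed)
    folds = kfold_split(pos, list(negatives), config.folds, seed=config.seed)
    per_fold: list[Metrics] = []
    for split in folds:
        _, metrics = train_fold(split, table, config, sequences, smiles)
        per_fold.append(metrics)
    names = ("auc", "aupr", "f1", "accuracy", "recall", "precision")
    summary = {
        "folds": [m.to_dict() for m in per_fold],
        "mean": {k: float(np.mean([m.to_dict()[k] for m in per_fold])) for k in names},
        "sd": {k: float(np.std([m.to_dict()[k] for m in per_fold], ddof=1)) for k in names},
    }
    return summary


def rank_candidates(
    est: TorsionGNNClassifier, query_circ_id: str, top_k: int = 20
) -> list[tuple[str, float]]:
    """Score all drugs not linked to the query in training; top_k descending.

    Ties break lexicographically by drug id.
    """
    est._check_fitted()
    graph = est.graph_
    if query_circ_id not in graph.circ_ids:
        raise KeyError(f"unknown circRNA id {query_circ_id!r}")
    known = {d for c, d in est.train_positive_pairs_ if c == query_circ_id}
    candidates = [d for d in graph.drug_ids if d not in known]
    if not candidates:
        return []
    scores = est.predict_proba([(query_circ_id, d) for d in candidates])[:, 1]
    ranked = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    return [(d, float(s)) for d, s in ranked[:top_k]]
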