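"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: spanning trees are counted
by exhaustive edge-subset enumeration, AUC by pairwise comparison, average
precision by the stepwise threshold definition, and message-passing layers by
explicit per-node loops.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def count_spanning_trees(nodes: list[int], edges: list[tuple[int, int]]) -> int:
    """Exhaustively count spanning trees of a connected graph."""
    n = len(nodes)
    if n == 1:
        return 1
    count = 0
    for subset in combinations(edges, n - 1):
        parent = {v: v for v in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        acyclic = True
        for u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                acyclic = False
                break
            parent[ru] = rv
        if acyclic:
            count += 1
    return count


def auc_pairwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the exhaustive pairwise win rate with half-credit for ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def average_precision_stepwise(scores: np.ndarray, labels: np.ndarray) -> float:
    """AP = sum over distinct descending thresholds of (R_i - R_{i-1}) * P_i."""
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    ap, tp, fp, prev_recall = 0.0, 0, 0, 0.0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += int((1 - y[i:j]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def threshold_metrics(scores: np.ndarray, labels: np.ndarray, thr: float = 0.5):
    """Accuracy / recall / precision / F1 straight from the confusion counts."""
    pred = (scores >= thr).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    acc = (tp + tn) / len(labels)
    rec = tp / (tp + fn) if tp + fn else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return acc, rec, prec, f1


def gcn_layer_loop(H, adj_sets, deg, w_edge, w_self, W, activation):
    """Per-node loop evaluation of the torsion-weighted propagation rule."""
    n = H.shape[0]
    out = np.zeros((n, W.shape[1]))
    for a in range(n):
        acc = np.zeros(W.shape[1])
        for b in adj_sets[a]:
            acc += (w_edge[(min(a, b), max(a, b))] / np.sqrt(deg[a] * deg[b])) * (W.T @ H[b])
        acc += (w_self[a] / deg[a]) * (W.T @ H[a])
        out[a] = acc
    return activation(out)


def gin_layer_loop(H, adj_sets, w_edge, eps, W1, b1, W2, b2, activation):
    n = H.shape[0]
    out = np.zeros((n, W2.shape[1]))
    for a in range(n):
        agg = (1 + eps) * H[a].copy()
        for b in adj_sets[a]:
            agg = agg + w_edge[(min(a, b), max(a, b))] * H[b]
        hidden = np.maximum(agg @ W1 + b1, 0.0)
        out[a] = hidden @ W2 + b2
    return activation(out)


def gat_layer_loop(H, adj_sets, w_edge, w_self, W, a_src, a_dst, activation, torsion=True):
    n = H.shape[0]
    HW = H @ W
    out = np.zeros_like(HW)
    for a in range(n):
        hood = sorted(adj_sets[a] | {a})
        logits = []
        for b in hood:
            e = a_src @ HW[a] + a_dst @ HW[b]
            e = e if e > 0 else 0.2 * e
            if torsion:
                e += w_self[a] if b == a else w_edge[(min(a, b), max(a, b))]
            logits.append(e)
        logits = np.array(logits)
        att = np.exp(logits - logits.max())
        att /= att.sum()
        out[a] = sum(att[i] * HW[b] for i, b in enumerate(hood))
    return activation(out)
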