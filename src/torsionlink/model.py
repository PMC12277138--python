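"""Torsion-weighted message-passing encoders, pair decoder, loss and trainer.

The GCN-style propagation rule is

    h_a = sigmoid( sum_{b in N(a) + {a}}  w(a, b) / sqrt(d_a d_b) * W h_b )

where d is the bipartite degree + 1 (self-loop convention), w(a, b) is the
log analytic torsion of the edge-centred subgraph around (a, b), and w(a, a)
the log-torsion of a's node-centred subgraph.  With torsion disabled w = 1
everywhere and the rule reduces to symmetric-normalised self-loop propagation.
The GAT variant injects log-torsion as an additive bias on attention logits;
the GIN variant uses it as a multiplicative neighbour weight.

A pair (u, v) is scored by an MLP over (h_u + h_v, h_u * h_v, h_u || h_v),
sized 4d -> d -> d/2 -> 1 with ReLU hidden layers and a sigmoid output,
trained with binary cross-entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .graph import BipartiteGraph, degrees
from .io import RunConfig
from .simplicial import TorsionCache

__all__ = [
    "build_propagation",
    "torsion_gcn_layer",
    "torsion_gat_layer",
    "torsion_gin_layer",
    "gat_attention",
    "encode",
    "decode_pair",
    "bce_loss",
    "TorsionGNN",
    "fit_network",
]

_ACTIVATIONS = {
    "sigmoid": lambda t: t.sigmoid(),
    "identity": lambda t: t,
    "relu": lambda t: t.relu(),
}


def _act_np(name: str, x: np.ndarray) -> np.ndarray:
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    if name == "identity":
        return x
    if name == "relu":
        return np.maximum(x, 0.0)
    raise ValueError(f"unknown activation {name!r}")


def _edge_weight_matrix(
    graph: BipartiteGraph, cache: TorsionCache, torsion_enabled: bool, with_self: bool
) -> np.ndarray:
    """(N+M)^2 matrix of w(a, b) on edges (and optionally w(a, a) on the diagonal)."""
    n = graph.n_nodes
    W = np.zeros((n, n), dtype=float)
    for u, v in graph.edges():
        w = cache.edge(u, v) if torsion_enabled else 1.0
        W[u, v] = W[v, u] = w
    if with_self:
        for a in range(n):
            W[a, a] = cache.node(a) if torsion_enabled else 1.0
    return W


def build_propagation(
    graph: BipartiteGraph, cache: TorsionCache, torsion_enabled: bool = True
) -> np.ndarray:
    """Degree-normalised, torsion-weighted propagation matrix P.

    P[a, b] = w(a, b) / sqrt(d_a d_b) on edges and the diagonal; with torsion
    off this is exactly D^{-1/2} (A + I) D^{-1/2}.
    """
    W = _edge_weight_matrix(graph, cache, torsion_enabled, with_self=True)
    d = degrees(graph)
    inv_sqrt = 1.0 / np.sqrt(d)
    return inv_sqrt[:, None] * W * inv_sqrt[None, :]


def torsion_gcn_layer(
    H_prev: np.ndarray,
    graph: BipartiteGraph,
    cache: TorsionCache,
    W: np.ndarray,
    torsion_enabled: bool = True,
    activation: str = "sigmoid",
) -> np.ndarray:
    """One torsion-weighted GCN layer (numpy forward pass)."""
    P = build_propagation(graph, cache, torsion_enabled)
    Z = P @ np.asarray(H_prev, dtype=float) @ np.asarray(W, dtype=float)
    return _act_np(activation, Z)


def gat_attention(
    H_prev: np.ndarray,
    graph: BipartiteGraph,
    cache: TorsionCache,
    params: dict[str, np.ndarray],
    torsion_enabled: bool = True,
) -> np.ndarray:
    """Row-stochastic attention matrix over each node's closed neighbourhood.

    Single-head attention with leaky-ReLU logits; when torsion is enabled the
    log-torsion of the (a, b) subgraph is added to the logit before the softmax.
    """
    HW = np.asarray(H_prev, dtype=float) @ params["W"]
    s_src = HW @ params["a_src"]
    s_dst = HW @ params["a_dst"]
    E = s_src[:, None] + s_dst[None, :]
    E = np.where(E > 0, E, 0.2 * E)  # leaky ReLU, slope 0.2
    if torsion_enabled:
        E = E + _edge_weight_matrix(graph, cache, True, with_self=True)
    mask = _edge_weight_matrix(graph, cache, False, with_self=True) > 0
    E = np.where(mask, E, -np.inf)
    E -= E.max(axis=1, keepdims=True)
    ex = np.exp(E) * mask
    return ex / ex.sum(axis=1, keepdims=True)


def torsion_gat_layer(
    H_prev: np.ndarray,
    graph: BipartiteGraph,
    cache: TorsionCache,
    params: dict[str, np.ndarray],
    torsion_enabled: bool = True,
    activation: str = "sigmoid",
) -> np.ndarray:
    """One torsion-biased attention layer (numpy forward pass)."""
    att = gat_attention(H_prev, graph, cache, params, torsion_enabled)
    return _act_np(activation, att @ (np.asarray(H_prev, dtype=float) @ params["W"]))


def torsion_gin_layer(
    H_prev: np.ndarray,
    graph: BipartiteGraph,
    cache: TorsionCache,
    params: dict[str, np.ndarray],
    torsion_enabled: bool = True,
    activation: str = "sigmoid",
) -> np.ndarray:
    """One torsion-weighted GIN layer: MLP((1 + eps) h_a + sum_b w(a,b) h_b)."""
    H = np.asarray(H_prev, dtype=float)
    Wadj = _edge_weight_matrix(graph, cache, torsion_enabled, with_self=False)
    agg = (1.0 + float(params["eps"])) * H + Wadj @ H
    hidden = np.maximum(agg @ params["W1"] + params["b1"], 0.0)
    return _act_np(activation, hidden @ params["W2"] + params["b2"])


def decode_pair(h_u: np.ndarray, h_v: np.ndarray, dec: dict[str, np.ndarray]) -> np.ndarray:
    """Score pairs from embeddings via the (sum, product, concatenation) MLP."""
    h_u, h_v = np.atleast_2d(h_u), np.atleast_2d(h_v)
    if h_u.shape != h_v.shape:
        raise ValueError("embedding dimensions must match")
    x = np.concatenate([h_u + h_v, h_u * h_v, h_u, h_v], axis=1)
    z = np.maximum(x @ dec["W1"] + dec["b1"], 0.0)
    z = np.maximum(z @ dec["W2"] + dec["b2"], 0.0)
    return _act_np("sigmoid", z @ dec["W3"] + dec["b3"]).ravel()


def bce_loss(preds: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy; preds in (0, 1), labels in {0, 1}."""
    p = np.asarray(preds, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.size == 0:
        raise ValueError("bce_loss requires at least one prediction")
    if p.shape != y.shape:
        raise ValueError("preds and labels must have equal length")
    eps = 1e-12
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# trainable network
# ---------------------------------------------------------------------------


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _layer_dims(feat_dim: int, hidden: int, out: int, layers: int) -> list[tuple[int, int]]:
    if layers == 1:
        return [(feat_dim, out)]
    dims = [(feat_dim, hidden)]
    dims += [(hidden, hidden)] * (layers - 2)
    dims.append((hidden, out))
    return dims


@dataclass
class TorsionGNN:
    """Encoder + decoder with parameters as autodiff tensors.

    Propagation constants (the torsion-weighted propagation matrix for GCN, the
    neighbourhood mask and logit bias for GAT, the weighted adjacency for GIN)
    are precomputed from the training graph and its torsion cache.
    """

    config: RunConfig
    params: dict[str, ad.Tensor]
    consts: dict[str, np.ndarray]
    activation: str = "sigmoid"

    @classmethod
    def initialise(
        cls,
        graph: BipartiteGraph,
        cache: TorsionCache,
        feat_dim: int,
        config: RunConfig,
        rng: np.random.Generator,
        activation: str = "sigmoid",
    ) -> "TorsionGNN":
        p: dict[str, ad.Tensor] = {}
        dims = _layer_dims(feat_dim, config.hidden_dim, config.out_dim, config.layers)
        for layer, (din, dout) in enumerate(dims):
            if config.encoder == "gcn":
                p[f"enc{layer}.W"] = ad.Tensor(_glorot(rng, din, dout), requires_grad=True)
            elif config.encoder == "gat":
                p[f"enc{layer}.W"] = ad.Tensor(_glorot(rng, din, dout), requires_grad=True)
                p[f"enc{layer}.a_src"] = ad.Tensor(
                    _glorot(rng, dout, 1).ravel(), requires_grad=True
                )
                p[f"enc{layer}.a_dst"] = ad.Tensor(
                    _glorot(rng, dout, 1).ravel(), requires_grad=True
                )
            elif config.encoder == "gin":
                p[f"enc{layer}.W1"] = ad.Tensor(_glorot(rng, din, dout), requires_grad=True)
                p[f"enc{layer}.b1"] = ad.Tensor(np.zeros(dout), requires_grad=True)
                p[f"enc{layer}.W2"] = ad.Tensor(_glorot(rng, dout, dout), requires_grad=True)
                p[f"enc{layer}.b2"] = ad.Tensor(np.zeros(dout), requires_grad=True)
                p[f"enc{layer}.eps"] = ad.Tensor(np.zeros(()), requires_grad=True)
        d = config.out_dim
        h1, h2 = d, max(d // 2, 1)
        p["dec.W1"] = ad.Tensor(_glorot(rng, 4 * d, h1), requires_grad=True)
        p["dec.b1"] = ad.Tensor(np.zeros(h1), requires_grad=True)
        p["dec.W2"] = ad.Tensor(_glorot(rng, h1, h2), requires_grad=True)
        p["dec.b2"] = ad.Tensor(np.zeros(h2), requires_grad=True)
        p["dec.W3"] = ad.Tensor(_glorot(rng, h2, 1), requires_grad=True)
        p["dec.b3"] = ad.Tensor(np.zeros(1), requires_grad=True)

        consts: dict[str, np.ndarray] = {}
        enabled = config.torsion_enabled
        if config.encoder == "gcn":
            consts["prop"] = build_propagation(graph, cache, enabled)
        elif config.encoder == "gat":
            consts["mask"] = _edge_weight_matrix(graph, cache, False, with_self=True) > 0
            consts["bias"] = (
                _edge_weight_matrix(graph, cache, True, with_self=True)
                if enabled
                else np.zeros((graph.n_nodes, graph.n_nodes))
            )
        elif config.encoder == "gin":
            consts["wadj"] = _edge_weight_matrix(graph, cache, enabled, with_self=False)
        return cls(config=config, params=p, consts=consts, activation=activation)

    # -- forward ------------------------------------------------------------
    def _encode_t(self, H0: ad.Tensor) -> ad.Tensor:
        act = _ACTIVATIONS[self.activation]
        H = H0
        for layer in range(self.config.layers):
            if self.config.encoder == "gcn":
                prop = ad.Tensor(self.consts["prop"])
                H = act(prop @ H @ self.params[f"enc{layer}.W"])
            elif self.config.encoder == "gat":
                HW = H @ self.params[f"enc{layer}.W"]
                s_src = HW @ self.params[f"enc{layer}.a_src"].reshape(-1, 1)
                s_dst = HW @ self.params[f"enc{layer}.a_dst"].reshape(-1, 1)
                E = (s_src + s_dst.T).leaky_relu(0.2) + ad.Tensor(self.consts["bias"])
                mask = self.consts["mask"]
                shift = np.where(mask, E.data, -np.inf).max(axis=1, keepdims=True)
                ex = (E - ad.Tensor(shift)).exp() * ad.Tensor(mask.astype(float))
                att = ex / ex.sum(axis=1, keepdims=True)
                H = act(att @ HW)
            else:  # gin
                wadj = ad.Tensor(self.consts["wadj"])
                eps = self.params[f"enc{layer}.eps"]
                agg = H * (eps + 1.0) + wadj @ H
                hidden = (
                    agg @ self.params[f"enc{layer}.W1"] + self.params[f"enc{layer}.b1"]
                ).relu()
                H = act(hidden @ self.params[f"enc{layer}.W2"] + self.params[f"enc{layer}.b2"])
        return H

    def _decode_t(self, H: ad.Tensor, u_idx: np.ndarray, v_idx: np.ndarray) -> ad.Tensor:
        hu, hv = H.gather(u_idx), H.gather(v_idx)
        x = ad.concat([hu + hv, hu * hv, hu, hv], axis=1)
        z = (x @ self.params["dec.W1"] + self.params["dec.b1"]).relu()
        z = (z @ self.params["dec.W2"] + self.params["dec.b2"]).relu()
        return (z @ self.params["dec.W3"] + self.params["dec.b3"]).sigmoid().reshape(-1)

    def forward(self, H0: np.ndarray, u_idx: np.ndarray, v_idx: np.ndarray) -> ad.Tensor:
        return self._decode_t(self._encode_t(ad.Tensor(H0)), u_idx, v_idx)

    def embeddings(self, H0: np.ndarray) -> np.ndarray:
        return self._encode_t(ad.Tensor(H0)).data

    def predict(self, H0: np.ndarray, pairs_idx: np.ndarray) -> np.ndarray:
        pairs_idx = np.asarray(pairs_idx, dtype=np.intp)
        return self.forward(H0, pairs_idx[:, 0], pairs_idx[:, 1]).data

    def state(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.params.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = state[k].copy()


def encode(
    H0: np.ndarray,
    graph: BipartiteGraph,
    cache: TorsionCache,
    config: RunConfig,
    net: TorsionGNN | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply the configured stack of encoder layers; returns (N+M) x out_dim."""
    if net is None:
        rng = rng or np.random.default_rng(config.seed)
        net = TorsionGNN.initialise(graph, cache, H0.shape[1], config, rng)
    return net.embeddings(H0)


class _Adam:
    def __init__(self, params: dict[str, ad.Tensor], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.data) for k, t in params.items()}

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    def step(self) -> None:
        self.t += 1
        for k, t in self.params.items():
            if t.grad is None:
                continue
            g = t.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            m_hat = self.m[k] / (1 - self.b1**self.t)
            v_hat = self.v[k] / (1 - self.b2**self.t)
            t.data = t.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)


def _bce_t(p: ad.Tensor, y: np.ndarray) -> ad.Tensor:
    eps = 1e-7
    y_t = ad.Tensor(y)
    p_safe = p * (1 - 2 * eps) + eps  # keep the log arguments strictly inside (0, 1)
    return -(y_t * p_safe.log() + (1.0 - y_t) * (1.0 - p_safe).log()).mean()


def fit_network(
    graph: BipartiteGraph,
    cache: TorsionCache,
    H0: np.ndarray,
    pairs_idx: np.ndarray,
    labels: np.ndarray,
    config: RunConfig,
    seed: int,
    patience: int = 50,
    val_fraction: float = 0.1,
    activation: str = "sigmoid",
) -> tuple[TorsionGNN, TrainHistory]:
    """Full-batch Adam training of the encoder + decoder on labelled pairs.

    A fraction of the training pairs is held out for early stopping (best
    validation loss, given patience); with too few pairs for a split the model
    trains for the full epoch budget.
    """
    rng = np.random.default_rng(seed)
    pairs_idx = np.asarray(pairs_idx, dtype=np.intp)
    labels = np.asarray(labels, dtype=float)
    if pairs_idx.shape[0] != labels.shape[0]:
        raise ValueError("pairs and labels must have equal length")
    net = TorsionGNN.initialise(graph, cache, H0.shape[1], config, rng, activation)
    n = pairs_idx.shape[0]
    n_val = int(round(n * val_fraction))
    order = rng.permutation(n)
    val_ix, train_ix = order[:n_val], order[n_val:]
    use_val = n_val >= 2 and len(np.unique(labels[val_ix])) == 2
    if not use_val:
        train_ix = order
    opt = _Adam(net.params, config.lr)
    history = TrainHistory()
    best_val = np.inf
    best_state = net.state()
    stale = 0
    tu, tv = pairs_idx[train_ix, 0], pairs_idx[train_ix, 1]
    ty = labels[train_ix]
    for _ in range(config.epochs):
        opt.zero_grad()
        loss = _bce_t(net.forward(H0, tu, tv), ty)
        loss.backward()
        opt.step()
        history.train_loss.append(float(loss.data))
        if use_val:
            with np.errstate(over="ignore"):
                val_pred = net.forward(H0, pairs_idx[val_ix, 0], pairs_idx[val_ix, 1]).data
            val = bce_loss(val_pred, labels[val_ix])
            history.val_loss.append(val)
            if val < best_val - 1e-6:
                best_val = val
                best_state = net.state()
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if use_val:
        net.load_state(best_state)
    return net, history
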