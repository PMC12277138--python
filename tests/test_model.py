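import numpy as np
import pytest

from torsionlink.graph import build_graph, degrees
from torsionlink.io import AssociationTable, RunConfig
from torsionlink.model import (
    TorsionGNN,
    bce_loss,
    decode_pair,
    fit_network,
    gat_attention,
    torsion_gat_layer,
    torsion_gcn_layer,
    torsion_gin_layer,
)
from torsionlink.simplicial import torsion_weights

from _oracles import gat_layer_loop, gcn_layer_loop, gin_layer_loop
from conftest import random_bipartite


def _identity(x):
    return x


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _cache_and_adj(g, enabled=True):
    cache = torsion_weights(g, 1, 1, enabled=enabled)
    adj = [set(g.neighbors(i)) for i in range(g.n_nodes)]
    return cache, adj


@pytest.mark.parametrize("seed", range(5))
def test_gcn_reduction_to_normalised_propagation(seed):
    """Torsion off + identity activation == D^-1/2 (A+I) D^-1/2 H W."""
    rng = np.random.default_rng(seed)
    g = random_bipartite(rng, 5, 4, 0.4)
    cache, _ = _cache_and_adj(g, enabled=False)
    H = rng.standard_normal((g.n_nodes, 3))
    W = rng.standard_normal((3, 2))
    out = torsion_gcn_layer(H, g, cache, W, torsion_enabled=False, activation="identity")
    n = g.n_circ
    A_sym = np.zeros((g.n_nodes, g.n_nodes))
    A_sym[:n, n:] = g.A
    A_sym[n:, :n] = g.A.T
    A_tilde = A_sym + np.eye(g.n_nodes)
    D = np.diag(1.0 / np.sqrt(A_tilde.sum(axis=1)))
    assert np.allclose(out, D @ A_tilde @ D @ H @ W, atol=1e-9)


@pytest.mark.parametrize("seed", range(5))
def test_gcn_layer_matches_loop_oracle(seed):
    rng = np.random.default_rng(50 + seed)
    g = random_bipartite(rng, 5, 5, 0.4)
    cache, adj = _cache_and_adj(g)
    H = rng.standard_normal((g.n_nodes, 3))
    W = rng.standard_normal((3, 2))
    out = torsion_gcn_layer(H, g, cache, W, activation="sigmoid")
    expect = gcn_layer_loop(
        H, adj, degrees(g), cache.edge_weights, cache.node_weights, W, _sigmoid
    )
    assert np.allclose(out, expect, atol=1e-9)
    assert ((out > 0) & (out < 1)).all()


@pytest.mark.parametrize("seed", range(5))
def test_gin_layer_matches_loop_oracle(seed):
    rng = np.random.default_rng(150 + seed)
    g = random_bipartite(rng, 4, 4, 0.5)
    cache, adj = _cache_and_adj(g)
    H = rng.standard_normal((g.n_nodes, 3))
    params = {
        "eps": 0.3,
        "W1": rng.standard_normal((3, 4)),
        "b1": rng.standard_normal(4),
        "W2": rng.standard_normal((4, 2)),
        "b2": rng.standard_normal(2),
    }
    out = torsion_gin_layer(H, g, cache, params, activation="sigmoid")
    expect = gin_layer_loop(
        H, adj, cache.edge_weights, params["eps"], params["W1"], params["b1"],
        params["W2"], params["b2"], _sigmoid,
    )
    assert np.allclose(out, expect, atol=1e-9)


def test_gin_reduces_to_plain_sum_aggregation():
    """w == 1 and eps = 0 gives MLP(h_a + sum_b h_b); isolated node gives MLP(h_a)."""
    g = build_graph(AssociationTable(records=(("c1", "d1", 1), ("c2", "d1", 0))))
    cache, _ = _cache_and_adj(g, enabled=False)
    rng = np.random.default_rng(0)
    H = rng.standard_normal((3, 2))
    params = {
        "eps": 0.0,
        "W1": np.eye(2),
        "b1": np.zeros(2),
        "W2": np.eye(2),
        "b2": np.zeros(2),
    }
    out = torsion_gin_layer(H, g, cache, params, torsion_enabled=False, activation="identity")
    agg0 = H[0] + H[2]  # c1 aggregates itself + d1
    assert np.allclose(out[0], np.maximum(agg0, 0))
    assert np.allclose(out[1], np.maximum(H[1], 0))  # isolated c2


@pytest.mark.parametrize("seed", range(5))
def test_gat_layer_matches_loop_oracle(seed):
    rng = np.random.default_rng(250 + seed)
    g = random_bipartite(rng, 4, 5, 0.4)
    cache, adj = _cache_and_adj(g)
    H = rng.standard_normal((g.n_nodes, 3))
    params = {
        "W": rng.standard_normal((3, 2)),
        "a_src": rng.standard_normal(2),
        "a_dst": rng.standard_normal(2),
    }
    out = torsion_gat_layer(H, g, cache, params, activation="sigmoid")
    expect = gat_layer_loop(
        H, adj, cache.edge_weights, cache.node_weights,
        params["W"], params["a_src"], params["a_dst"], _sigmoid, torsion=True,
    )
    assert np.allclose(out, expect, atol=1e-9)


def test_gat_attention_rows_sum_to_one_and_uniform_case():
    g = build_graph(
        AssociationTable(records=(("c1", "d1", 1), ("c1", "d2", 1), ("c2", "d1", 1)))
    )
    cache, _ = _cache_and_adj(g, enabled=False)
    H = np.ones((g.n_nodes, 3))
    params = {"W": np.zeros((3, 2)), "a_src": np.zeros(2), "a_dst": np.zeros(2)}
    att = gat_attention(H, g, cache, params, torsion_enabled=False)
    assert np.allclose(att.sum(axis=1), 1.0, atol=1e-9)
    # equal logits, no torsion bias -> uniform over each closed neighbourhood
    row = att[0]
    hood = sorted(g.neighbors(0) | {0})
    assert np.allclose(row[hood], 1.0 / len(hood))


def test_decode_pair_input_structure():
    """The decoder consumes (h_u + h_v, h_u * h_v, h_u || h_v), length 4d."""
    h_u, h_v = np.array([1.0, 0.0]), np.array([0.0, 1.0])
    expected_x = np.array([1, 1, 0, 0, 1, 0, 0, 1], dtype=float)
    # identity-passthrough MLP reveals x: W1 = I8, W2 = I8, W3 = e_k
    dec = {
        "W1": np.eye(8), "b1": np.zeros(8),
        "W2": np.eye(8), "b2": np.zeros(8),
        "W3": np.zeros((8, 1)), "b3": np.zeros(1),
    }
    for k, xk in enumerate(expected_x):
        dec["W3"] = np.zeros((8, 1))
        dec["W3"][k, 0] = 1.0
        out = decode_pair(h_u, h_v, dec)[0]
        assert out == pytest.approx(_sigmoid(xk))
    assert 0.0 < out < 1.0


def test_bce_loss_closed_forms():
    assert bce_loss(np.array([0.5, 0.5]), np.array([1, 0])) == pytest.approx(np.log(2))
    assert bce_loss(np.array([0.999, 0.001]), np.array([1, 0])) == pytest.approx(0.0, abs=1e-2)
    with pytest.raises(ValueError):
        bce_loss(np.array([]), np.array([]))
    rng = np.random.default_rng(0)
    p = rng.uniform(0.01, 0.99, size=20)
    y = rng.integers(0, 2, size=20)
    expect = -np.mean([yy * np.log(pp) + (1 - yy) * np.log(1 - pp) for pp, yy in zip(p, y)])
    assert bce_loss(p, y) == pytest.approx(expect, abs=1e-12)


@pytest.mark.parametrize("encoder", ["gcn", "gat", "gin"])
def test_network_forward_matches_layer_functions(encoder):
    """The autodiff forward pass agrees with the numpy layer composition."""
    rng = np.random.default_rng(9)
    g = random_bipartite(rng, 4, 4, 0.5)
    cache = torsion_weights(g, 1, 1)
    cfg = RunConfig(encoder=encoder, layers=2, hidden_dim=5, out_dim=3)
    net = TorsionGNN.initialise(g, cache, 4, cfg, np.random.default_rng(0))
    H0 = rng.standard_normal((g.n_nodes, 4))
    H = H0
    for layer in range(2):
        if encoder == "gcn":
            H = torsion_gcn_layer(H, g, cache, net.params[f"enc{layer}.W"].data)
        elif encoder == "gat":
            params = {
                "W": net.params[f"enc{layer}.W"].data,
                "a_src": net.params[f"enc{layer}.a_src"].data,
                "a_dst": net.params[f"enc{layer}.a_dst"].data,
            }
            H = torsion_gat_layer(H, g, cache, params)
        else:
            params = {
                "eps": float(net.params[f"enc{layer}.eps"].data),
                "W1": net.params[f"enc{layer}.W1"].data,
                "b1": net.params[f"enc{layer}.b1"].data,
                "W2": net.params[f"enc{layer}.W2"].data,
                "b2": net.params[f"enc{layer}.b2"].data,
            }
            H = torsion_gin_layer(H, g, cache, params)
    assert np.allclose(net.embeddings(H0), H, atol=1e-9)


def test_training_reduces_loss_on_separable_toy():
    rng = np.random.default_rng(4)
    table = AssociationTable(
        records=tuple((f"c{i}", f"d{i}", 1) for i in range(5))
        + tuple((f"c{i}", f"d{(i+1) % 5}", 1) for i in range(5))
    )
    g = build_graph(table)
    cache = torsion_weights(g, 1, 1)
    from torsionlink.features import position_features

    H0 = position_features(g)
    pos = [(g.circ_index(c), g.drug_index(d)) for c, d, _ in table.records]
    neg = [(i, g.n_circ + ((i + 2) % 5)) for i in range(5)]
    pairs = np.array(pos + neg)
    labels = np.array([1.0] * len(pos) + [0.0] * len(neg))
    cfg = RunConfig(hidden_dim=16, out_dim=8, epochs=500, lr=1e-2)
    net, hist = fit_network(g, cache, H0, pairs, labels, cfg, seed=0, val_fraction=0.0)
    assert hist.train_loss[-1] < hist.train_loss[0] * 0.8


def test_decode_pair_dim_mismatch():
    with pytest.raises(ValueError):
        decode_pair(np.ones((1, 2)), np.ones((1, 3)), {})
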