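"""Per-node encoder operations and the vectorized full-graph forward pass."""

import numpy as np
import pytest

import eventlink as el
from eventlink.encoder import (FeaturePack, adjacency_matrix,
                               attention_aggregate, encode, init_encoder_params)

from conftest import random_graph

RNG = np.random.default_rng(2024)


# ---------------------------------------------------------------------------
# projection


def test_projection_identity_and_null_maps():
    H = RNG.standard_normal((3, 4))
    np.testing.assert_array_equal(el.project_features(H, np.eye(4)), H)
    np.testing.assert_array_equal(el.project_features(H, np.zeros((2, 4))), np.zeros((3, 2)))


def test_projection_matches_per_row_products():
    H, M = RNG.standard_normal((3, 5)), RNG.standard_normal((4, 5))
    out = el.project_features(H, M)
    for i in range(3):
        np.testing.assert_allclose(out[i], M @ H[i], atol=1e-12)
    with pytest.raises(ValueError):
        el.project_features(H, np.zeros((4, 6)))


# ---------------------------------------------------------------------------
# neighbor sampling


def test_sample_neighbors_underfull_and_subset(fixture_graph):
    _, _, graph = fixture_graph
    assert list(el.sample_neighbors(graph, 0, k=5, seed=0)) == [0, 1, 5]
    # disease 1 has two event neighbors
    assert list(el.sample_neighbors(graph, 1, k=5, seed=0, node_type="disease")) == [0, 1]


def test_sample_neighbors_subsample_and_determinism():
    rng = np.random.default_rng(3)
    graph = random_graph(rng, 4, 12, p=0.9)
    full = set(v for u, v in graph.edges if u == 0)
    s1 = el.sample_neighbors(graph, 0, k=3, seed=11)
    s2 = el.sample_neighbors(graph, 0, k=3, seed=11)
    assert len(s1) == 3 and set(s1) <= full
    np.testing.assert_array_equal(s1, s2)


# ---------------------------------------------------------------------------
# convolution update


def test_conv_update_isolated_node_reduces_to_self():
    h = RNG.standard_normal(4)
    W = RNG.standard_normal((4, 8))
    expect = np.maximum(W @ np.concatenate([h, h]), 0.0)
    np.testing.assert_allclose(el.conv_update(h, [], W), expect, atol=1e-12)


def test_conv_update_zero_inputs_give_zero():
    W = RNG.standard_normal((4, 8))
    np.testing.assert_array_equal(el.conv_update(np.zeros(4), [np.zeros(4)] * 3, W),
                                  np.zeros(4))


def test_conv_update_matches_scalar_evaluation():
    """Mean aggregate + FC + ReLU, hand-composed element by element."""
    h = RNG.standard_normal(4)
    nbrs = [RNG.standard_normal(4) for _ in range(3)]
    W = RNG.standard_normal((4, 8))
    z = (h + sum(nbrs)) / 4.0
    cat = np.concatenate([h, z])
    expect = np.array([max(0.0, sum(W[r, c] * cat[c] for c in range(8))) for r in range(4)])
    np.testing.assert_allclose(el.conv_update(h, nbrs, W), expect, atol=1e-12)


@pytest.mark.parametrize("agg,red", [("sum", np.sum), ("max", np.max)])
def test_conv_update_alternative_aggregators(agg, red):
    h = RNG.standard_normal(3)
    nbrs = [RNG.standard_normal(3) for _ in range(2)]
    W = RNG.standard_normal((3, 6))
    z = red(np.stack([h] + nbrs), axis=0)
    expect = np.maximum(W @ np.concatenate([h, z]), 0.0)
    np.testing.assert_allclose(el.conv_update(h, nbrs, W, aggregator=agg), expect, atol=1e-12)


# ---------------------------------------------------------------------------
# attention


def test_attention_singleton_and_symmetric_neighborhoods():
    h = RNG.standard_normal(4)
    Wv, a = RNG.standard_normal((4, 4)), RNG.standard_normal(8)
    u = RNG.standard_normal(4)
    np.testing.assert_allclose(el.attention_coefficients(h, [u], Wv, a), [1.0])
    np.testing.assert_allclose(el.attention_coefficients(h, [u, u], Wv, a), [0.5, 0.5])
    with pytest.raises(ValueError, match="empty neighborhood"):
        el.attention_coefficients(h, [], Wv, a)


def test_attention_matches_exp_normalize_oracle():
    h = RNG.standard_normal(4)
    nbrs = [RNG.standard_normal(4) for _ in range(3)]
    Wv, a = RNG.standard_normal((4, 4)), RNG.standard_normal(8)
    leaky = lambda x: x if x > 0 else 0.2 * x
    scores = np.array([leaky(a @ np.concatenate([Wv @ h, Wv @ hj])) for hj in nbrs])
    expect = np.exp(scores) / np.exp(scores).sum()
    got = el.attention_coefficients(h, nbrs, Wv, a)
    np.testing.assert_allclose(got, expect, atol=1e-12)
    assert abs(got.sum() - 1.0) < 1e-12


def test_attention_update_degenerate_and_fixed_point():
    h = RNG.standard_normal(3)
    nbrs = [RNG.standard_normal(3) for _ in range(3)]
    Wv = RNG.standard_normal((3, 3))
    # all weight on the first neighbor
    sem = attention_aggregate(nbrs, [1.0, 0.0, 0.0], Wv)
    np.testing.assert_allclose(sem, Wv @ nbrs[0], atol=1e-12)
    # identical neighbors: any normalized weights give the same aggregate
    u = RNG.standard_normal(3)
    sem2 = attention_aggregate([u, u, u], [0.2, 0.3, 0.5], Wv)
    np.testing.assert_allclose(sem2, Wv @ u, atol=1e-12)


def test_attention_update_matches_summation_oracle():
    h = RNG.standard_normal(3)
    nbrs = [RNG.standard_normal(3) for _ in range(4)]
    Wv = RNG.standard_normal((3, 3))
    U = RNG.standard_normal((3, 6))
    w = np.abs(RNG.standard_normal(4))
    w = w / w.sum()
    sem = sum(wi * (Wv @ hj) for wi, hj in zip(w, nbrs))
    expect = U @ np.maximum(np.concatenate([h, sem]), 0.0)
    np.testing.assert_allclose(el.attention_update(h, nbrs, w, Wv, U), expect, atol=1e-12)


# ---------------------------------------------------------------------------
# gate


def test_gate_half_passthrough_and_saturation():
    h = RNG.standard_normal(5)
    np.testing.assert_allclose(el.gate(h, np.zeros((5, 5)), np.zeros(5)), 0.5 * h)
    out = el.gate(h, np.zeros((5, 5)), np.full(5, 8.0))
    np.testing.assert_allclose(out, h, rtol=4e-4)


def test_gate_matches_direct_formula_and_bounds():
    h = RNG.standard_normal(4)
    W, b = RNG.standard_normal((4, 4)), RNG.standard_normal(4)
    expect = h * (1.0 / (1.0 + np.exp(-(W @ h + b))))
    got = el.gate(h, W, b)
    np.testing.assert_allclose(got, expect, atol=1e-12)
    assert (np.abs(got) <= np.abs(h) + 1e-15).all()


# ---------------------------------------------------------------------------
# full encode


def straight_line_encode(graph, features, params):
    """Independent per-node evaluation of one full encoder pass (no sampling:
    call with k >= max degree so the conv branch sees every neighbor)."""
    X_e = features.event_onehot
    if params.event_embed is not None:
        X_e = np.concatenate([features.event_onehot, params.event_embed], axis=1)
    He = X_e @ params.M["event"].T
    Hd = features.disease @ params.M["disease"].T
    adj = adjacency_matrix(graph.n_events, graph.n_diseases, graph.edges)
    for lp in params.layers:
        new_e = np.zeros_like(He)
        new_d = np.zeros_like(Hd)
        for t, H_self, H_other, A in (("event", He, Hd, adj), ("disease", Hd, He, adj.T)):
            out = np.zeros_like(H_self)
            for i in range(H_self.shape[0]):
                nbrs = [H_other[j] for j in np.flatnonzero(A[i])]
                total = H_self[i].copy()
                if params.use_conv:
                    c = el.conv_update(H_self[i], nbrs, lp.W, params.aggregator)
                    if params.use_gate:
                        c = el.gate(c, lp.gate_conv_W, lp.gate_conv_b)
                    total = total + c
                if params.use_attention:
                    if nbrs:
                        w = el.attention_coefficients(H_self[i], nbrs, lp.W_att[t], lp.a[t],
                                                      params.leaky_slope)
                        at = el.attention_update(H_self[i], nbrs, w, lp.W_att[t], lp.U)
                    else:
                        at = lp.U @ np.maximum(np.concatenate([H_self[i], np.zeros(params.d)]), 0.0)
                    if params.use_gate:
                        at = el.gate(at, lp.gate_att_W, lp.gate_att_b)
                    total = total + at
                out[i] = total
            if t == "event":
                new_e = out
            else:
                new_d = out
        He, Hd = new_e, new_d
    return He, Hd


@pytest.mark.parametrize("flags", [
    dict(),                                         # full model
    dict(use_attention=False),                      # conv branch only
    dict(use_conv=False),                           # attention branch only
    dict(use_gate=False),
    dict(aggregator="sum"),
])
def test_encode_matches_straight_line_reimplementation(flags):
    """Vectorized forward equals per-node composition of the reference ops."""
    rng = np.random.default_rng(17)
    graph = random_graph(rng, 4, 5, p=0.5)
    feats = FeaturePack(event_onehot=adjacency_matrix(4, 5, graph.edges),
                        disease=rng.standard_normal((5, 3)))
    params = init_encoder_params(4, 5, 3, d=4, n_layers=2, event_embed_dim=2, seed=1,
                                 k=100, **flags)
    emb = encode(graph, feats, params, seed=0)
    He, Hd = straight_line_encode(graph, feats, params)
    np.testing.assert_allclose(emb.event, He, atol=1e-9)
    np.testing.assert_allclose(emb.disease, Hd, atol=1e-9)


def test_encode_permutation_equivariance():
    """Relabeling events permutes event embedding rows identically."""
    rng = np.random.default_rng(5)
    graph = random_graph(rng, 5, 6, p=0.5)
    feats = FeaturePack(event_onehot=adjacency_matrix(5, 6, graph.edges),
                        disease=rng.standard_normal((6, 3)))
    params = init_encoder_params(5, 6, 3, d=4, n_layers=1, event_embed_dim=0, seed=2, k=100)
    perm = np.array([2, 0, 4, 1, 3])
    inv = np.argsort(perm)
    g2 = el.HeteroGraph(5, 6, tuple(sorted((int(inv[u]), v) for u, v in graph.edges)),
                        tuple(graph.event_annotations[p] for p in perm))
    f2 = FeaturePack(event_onehot=feats.event_onehot[perm], disease=feats.disease)
    emb1 = encode(graph, feats, params, seed=0)
    emb2 = encode(g2, f2, params, seed=0)
    np.testing.assert_allclose(emb2.event, emb1.event[perm], atol=1e-9)
    np.testing.assert_allclose(emb2.disease, emb1.disease, atol=1e-9)


def test_encode_residual_only_limit():
    """All-zero weights with zero gates leave only the residual path: the
    embeddings equal the projected inputs at any depth."""
    rng = np.random.default_rng(8)
    graph = random_graph(rng, 3, 4, p=0.6)
    feats = FeaturePack(event_onehot=adjacency_matrix(3, 4, graph.edges),
                        disease=rng.standard_normal((4, 2)))
    params = init_encoder_params(3, 4, 2, d=3, n_layers=2, event_embed_dim=0, seed=0, k=10)
    for lp in params.layers:
        lp.W[:] = 0; lp.U[:] = 0
        for t in lp.W_att:
            lp.W_att[t][:] = 0; lp.a[t][:] = 0
        lp.gate_conv_W[:] = 0; lp.gate_conv_b[:] = -50.0   # gates shut
        lp.gate_att_W[:] = 0; lp.gate_att_b[:] = -50.0
    emb = encode(graph, feats, params, seed=0)
    np.testing.assert_allclose(emb.event, feats.event_onehot @ params.M["event"].T, atol=1e-9)
    np.testing.assert_allclose(emb.disease, feats.disease @ params.M["disease"].T, atol=1e-9)


def test_encode_deterministic_and_dropout_free_at_eval():
    rng = np.random.default_rng(9)
    graph = random_graph(rng, 6, 7, p=0.4)
    feats = FeaturePack(event_onehot=adjacency_matrix(6, 7, graph.edges),
                        disease=rng.standard_normal((7, 3)))
    params = init_encoder_params(6, 7, 3, d=4, n_layers=2, seed=3, k=2, dropout=0.5)
    e1 = encode(graph, feats, params, seed=42)
    e2 = encode(graph, feats, params, seed=42)
    np.testing.assert_array_equal(e1.event, e2.event)
    np.testing.assert_array_equal(e1.disease, e2.disease)


def test_encoder_requires_at_least_one_layer():
    with pytest.raises(ValueError):
        init_encoder_params(3, 4, 2, d=3, n_layers=0)
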