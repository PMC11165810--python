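"""Gated convolution + attention encoder over the event-disease graph.

Each layer runs two branches in parallel on every node and fuses them:

* a sample-and-aggregate convolution branch — up to ``k`` neighbors are drawn
  uniformly, aggregated (mean by default) together with the node itself, and
  the concatenation of the node state and the aggregate is passed through a
  fully connected layer with ReLU;
* a typed attention branch — neighbors are scored with a single-head additive
  attention (LeakyReLU slope 0.2, softmax-normalized), their transformed
  states are averaged under those weights into a semantic representation,
  which is concatenated with the node state, rectified and mapped back to
  width ``d``.

Each branch output passes through a gate ``x * sigmoid(W x + b)`` and the two
gated branches are summed with a residual connection from the layer input.
Event raw features are the one-hot event-disease rows, optionally concatenated
with a trainable free embedding; disease raw features are random normals.
Both are projected to the shared width ``d`` by per-type linear maps before
the first layer.

This module exposes two faces: per-node reference operations
(:func:`conv_update`, :func:`attention_coefficients`, :func:`gate`, ...) used
in tests and documentation, and the vectorized :func:`encode` used by training
(autodiff-backed internally, verified against the per-node forms).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Tensor, concat, glorot
from .graph import HeteroGraph

NODE_TYPES = ("event", "disease")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class LayerParams:
    W: np.ndarray                    # (d, 2d) convolution fully connected layer
    W_att: dict[str, np.ndarray]     # per type (d, d) attention transform
    a: dict[str, np.ndarray]         # per type (2d,) attention vector
    U: np.ndarray                    # (d, 2d) post-concat map of the attention branch
    gate_conv_W: np.ndarray          # (d, d)
    gate_conv_b: np.ndarray          # (d,)
    gate_att_W: np.ndarray
    gate_att_b: np.ndarray


@dataclass
class EncoderParams:
    """All learnable arrays plus the structural knobs of the encoder."""

    M: dict[str, np.ndarray]          # per-type projection (d, in_dim)
    layers: list[LayerParams]
    event_embed: np.ndarray | None = None   # (q, e_dim) trainable free features
    d: int = 64
    k: int = 10                       # neighbor sample size of the conv branch
    dropout: float = 0.0
    aggregator: str = "mean"          # mean | sum
    leaky_slope: float = 0.2
    use_conv: bool = True
    use_attention: bool = True
    use_gate: bool = True

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def copy(self) -> "EncoderParams":
        layers = [LayerParams(
            l.W.copy(), {t: m.copy() for t, m in l.W_att.items()},
            {t: v.copy() for t, v in l.a.items()}, l.U.copy(),
            l.gate_conv_W.copy(), l.gate_conv_b.copy(),
            l.gate_att_W.copy(), l.gate_att_b.copy()) for l in self.layers]
        return replace(self, M={t: m.copy() for t, m in self.M.items()}, layers=layers,
                       event_embed=None if self.event_embed is None else self.event_embed.copy())


@dataclass
class FeaturePack:
    """Raw node features: one-hot event rows and random disease vectors."""

    event_onehot: np.ndarray      # (q, z) binary
    disease: np.ndarray           # (z, dim)


@dataclass
class EmbeddingTable:
    event: np.ndarray             # (q, d)
    disease: np.ndarray           # (z, d)

    def __getitem__(self, node_type: str) -> np.ndarray:
        return getattr(self, node_type)


def init_encoder_params(n_events: int, event_in: int, disease_in: int, *, d: int = 64,
                        n_layers: int = 2, event_embed_dim: int | None = None,
                        seed: int = 0, **kwargs) -> EncoderParams:
    """Glorot-initialized parameters; `event_in` excludes the free embedding width."""
    if n_layers < 1:
        raise ValueError("encoder needs at least one layer")
    rng = np.random.default_rng(seed)
    e_dim = d if event_embed_dim is None else event_embed_dim
    event_embed = None
    if e_dim > 0:
        event_embed = rng.standard_normal((n_events, e_dim)) / np.sqrt(e_dim)
    M = {"event": glorot(rng, (d, event_in + e_dim)), "disease": glorot(rng, (d, disease_in))}
    layers = []
    for _ in range(n_layers):
        layers.append(LayerParams(
            W=glorot(rng, (d, 2 * d)),
            W_att={t: glorot(rng, (d, d)) for t in NODE_TYPES},
            a={t: glorot(rng, (2 * d,)) for t in NODE_TYPES},
            U=glorot(rng, (d, 2 * d)),
            gate_conv_W=glorot(rng, (d, d)), gate_conv_b=np.zeros(d),
            gate_att_W=glorot(rng, (d, d)), gate_att_b=np.zeros(d),
        ))
    return EncoderParams(M=M, layers=layers, event_embed=event_embed, d=d, **kwargs)


# ---------------------------------------------------------------------------
# per-node reference operations


def project_features(H: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Per-type linear projection h' = M h applied to every row of H."""
    H = np.atleast_2d(np.asarray(H, dtype=np.float64))
    if H.shape[1] != M.shape[1]:
        raise ValueError(f"feature width {H.shape[1]} does not match projection input {M.shape[1]}")
    return H @ M.T


def sample_neighbors(graph: HeteroGraph, node: int, k: int, seed: int,
                     node_type: str = "event") -> np.ndarray:
    """Uniform sample of min(k, degree) distinct neighbors; full set if degree <= k."""
    if node_type == "event":
        nbrs = np.array(sorted(v for u, v in graph.edges if u == node), dtype=int)
        if not 0 <= node < graph.n_events:
            raise ValueError(f"unknown event {node}")
    else:
        nbrs = np.array(sorted(u for u, v in graph.edges if v == node), dtype=int)
        if not 0 <= node < graph.n_diseases:
            raise ValueError(f"unknown disease {node}")
    if len(nbrs) <= k:
        return nbrs
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(nbrs, size=k, replace=False))


def conv_update(h_self: np.ndarray, neighbor_vectors, W: np.ndarray,
                aggregator: str = "mean") -> np.ndarray:
    """Sample-and-aggregate update: sigma(W [h_self || AGG({h_self} U neighbors)])."""
    h_self = np.asarray(h_self, dtype=np.float64)
    pool = [h_self] + [np.asarray(v, dtype=np.float64) for v in neighbor_vectors]
    stackd = np.stack(pool)
    if aggregator == "mean":
        z = stackd.mean(axis=0)
    elif aggregator == "sum":
        z = stackd.sum(axis=0)
    elif aggregator == "max":
        z = stackd.max(axis=0)
    else:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    return np.maximum(W @ np.concatenate([h_self, z]), 0.0)


def attention_coefficients(h_i: np.ndarray, neighbor_vectors, W_v: np.ndarray,
                           a: np.ndarray, slope: float = 0.2) -> np.ndarray:
    """Softmax-normalized additive attention weights over the neighborhood."""
    neighbor_vectors = [np.asarray(v, dtype=np.float64) for v in neighbor_vectors]
    if not neighbor_vectors:
        raise ValueError("attention undefined on empty neighborhood")
    ui = W_v @ np.asarray(h_i, dtype=np.float64)
    scores = []
    for hj in neighbor_vectors:
        s = a @ np.concatenate([ui, W_v @ hj])
        scores.append(s if s > 0 else slope * s)
    scores = np.asarray(scores)
    e = np.exp(scores - scores.max())
    return e / e.sum()


def attention_aggregate(neighbor_vectors, weights, W_v: np.ndarray) -> np.ndarray:
    """Semantic representation: attention-weighted sum of transformed neighbors."""
    out = np.zeros(W_v.shape[0])
    for w, hj in zip(weights, neighbor_vectors):
        out = out + w * (W_v @ np.asarray(hj, dtype=np.float64))
    return out


def attention_update(h_i: np.ndarray, neighbor_vectors, weights, W_v: np.ndarray,
                     out_map: np.ndarray | None = None) -> np.ndarray:
    """Fuse node state with the semantic representation.

    Returns sigma([h_i || h_i^sem]); if `out_map` is given the rectified concat
    is mapped back to width d (the form used inside the encoder layer).
    """
    sem = attention_aggregate(neighbor_vectors, weights, W_v)
    fused = np.maximum(np.concatenate([np.asarray(h_i, dtype=np.float64), sem]), 0.0)
    return fused if out_map is None else out_map @ fused


def gate(h: np.ndarray, W_gate: np.ndarray, b_gate: np.ndarray) -> np.ndarray:
    """Elementwise information gate h * sigmoid(W h + b)."""
    h = np.asarray(h, dtype=np.float64)
    pre = h @ W_gate.T + b_gate if h.ndim == 2 else W_gate @ h + b_gate
    return h * _sigmoid(pre)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


# ---------------------------------------------------------------------------
# vectorized forward (autodiff-backed)


@dataclass
class _TensorParams:
    M: dict[str, Tensor]
    layers: list[dict]
    event_embed: Tensor | None

    def all_tensors(self) -> list[Tensor]:
        out = list(self.M.values())
        if self.event_embed is not None:
            out.append(self.event_embed)
        for l in self.layers:
            for v in l.values():
                if isinstance(v, Tensor):
                    out.append(v)
                else:
                    out.extend(v.values())
        return out


def params_to_tensors(params: EncoderParams, requires_grad: bool) -> _TensorParams:
    T = lambda x: Tensor(x, requires_grad=requires_grad)
    layers = []
    for l in params.layers:
        layers.append({
            "W": T(l.W),
            "W_att": {t: T(m) for t, m in l.W_att.items()},
            "a": {t: T(v) for t, v in l.a.items()},
            "U": T(l.U),
            "gc_W": T(l.gate_conv_W), "gc_b": T(l.gate_conv_b),
            "ga_W": T(l.gate_att_W), "ga_b": T(l.gate_att_b),
        })
    return _TensorParams(
        M={t: T(m) for t, m in params.M.items()},
        layers=layers,
        event_embed=None if params.event_embed is None else T(params.event_embed),
    )


def tensors_to_params(tp: _TensorParams, template: EncoderParams) -> EncoderParams:
    out = template.copy()
    for t in NODE_TYPES:
        out.M[t] = tp.M[t].data.copy()
    out.event_embed = None if tp.event_embed is None else tp.event_embed.data.copy()
    for l_out, l_in in zip(out.layers, tp.layers):
        l_out.W = l_in["W"].data.copy()
        l_out.W_att = {t: l_in["W_att"][t].data.copy() for t in NODE_TYPES}
        l_out.a = {t: l_in["a"][t].data.copy() for t in NODE_TYPES}
        l_out.U = l_in["U"].data.copy()
        l_out.gate_conv_W = l_in["gc_W"].data.copy()
        l_out.gate_conv_b = l_in["gc_b"].data.copy()
        l_out.gate_att_W = l_in["ga_W"].data.copy()
        l_out.gate_att_b = l_in["ga_b"].data.copy()
    return out


def adjacency_matrix(n_events: int, n_diseases: int, edges) -> np.ndarray:
    B = np.zeros((n_events, n_diseases), dtype=np.float64)
    for u, v in edges:
        B[u, v] = 1.0
    return B


def _sample_adjacency(adj: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Row-wise uniform k-subset of a binary adjacency (full row when degree <= k)."""
    S = adj.copy()
    for i in range(adj.shape[0]):
        nbrs = np.flatnonzero(adj[i])
        if len(nbrs) > k:
            keep = rng.choice(nbrs, size=k, replace=False)
            S[i] = 0.0
            S[i, keep] = 1.0
    return S


def _masked_softmax_rows(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to mask==1 entries; all-zero rows give zero weights."""
    with np.errstate(invalid="ignore"):
        row_max = np.where(mask.any(axis=1),
                           np.max(np.where(mask > 0, scores.data, -np.inf), axis=1), 0.0)
    num = (scores - Tensor(row_max[:, None])).exp() * Tensor(mask)
    denom = num.sum(axis=1, keepdims=True) + Tensor((~mask.any(axis=1)).astype(float)[:, None])
    return num / denom


def _attention_branch(h_self: Tensor, h_nbr: Tensor, mask: np.ndarray, lp: dict,
                      node_type: str, slope: float) -> Tensor:
    Wv, a = lp["W_att"][node_type], lp["a"][node_type]
    d = Wv.shape[0]
    u_self = h_self @ _transpose(Wv)
    u_nbr = h_nbr @ _transpose(Wv)
    a_src = Tensor(np.eye(2 * d)[:d], requires_grad=False)  # split a into source/dest halves
    src = u_self @ (a_src @ a)          # (n,)
    dst = u_nbr @ (_dst_half(d) @ a)    # (m,)
    scores = (_col(src) + _row(dst)).leaky_relu(slope)
    alpha = _masked_softmax_rows(scores, mask)
    sem = alpha @ u_nbr
    fused = concat([h_self, sem], axis=1).relu()
    return fused @ _transpose(lp["U"])


def _transpose(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, _parents=(t,))
    out._backward = lambda g: (g.T,)
    return out


def _col(t: Tensor) -> Tensor:
    out = Tensor(t.data[:, None], _parents=(t,))
    out._backward = lambda g: (g[:, 0],)
    return out


def _row(t: Tensor) -> Tensor:
    out = Tensor(t.data[None, :], _parents=(t,))
    out._backward = lambda g: (g[0],)
    return out


def _dst_half(d: int) -> Tensor:
    return Tensor(np.eye(2 * d)[d:], requires_grad=False)


def _gate_t(h: Tensor, W: Tensor, b: Tensor) -> Tensor:
    return h * ((h @ _transpose(W)) + b).sigmoid()


def forward_embeddings(tp: _TensorParams, params: EncoderParams, features: FeaturePack,
                       mp_adj: np.ndarray, rng: np.random.Generator,
                       training: bool = False) -> tuple[Tensor, Tensor]:
    """Full-graph forward pass; `mp_adj` is the message-passing adjacency (q x z)."""
    X_e = Tensor(features.event_onehot)
    if tp.event_embed is not None:
        X_e = concat([X_e, tp.event_embed], axis=1)
    H = {
        "event": X_e @ _transpose(tp.M["event"]),
        "disease": Tensor(features.disease) @ _transpose(tp.M["disease"]),
    }
    adj = {"event": mp_adj, "disease": mp_adj.T}
    other = {"event": "disease", "disease": "event"}

    for li, lp in enumerate(tp.layers):
        new_H = {}
        for t in NODE_TYPES:
            h_in, h_nbr = H[t], H[other[t]]
            parts = []
            if params.use_conv:
                S = _sample_adjacency(adj[t], params.k, rng)
                counts = S.sum(axis=1) + 1.0
                agg = h_in + (Tensor(S) @ h_nbr)
                if params.aggregator == "mean":
                    agg = agg * Tensor(1.0 / counts[:, None])
                elif params.aggregator != "sum":
                    raise ValueError(f"aggregator {params.aggregator!r} not supported in encode")
                c = concat([h_in, agg], axis=1) @ _transpose(lp["W"])
                c = c.relu()
                if params.use_gate:
                    c = _gate_t(c, lp["gc_W"], lp["gc_b"])
                parts.append(c)
            if params.use_attention:
                at = _attention_branch(h_in, h_nbr, adj[t], lp, t, params.leaky_slope)
                if params.use_gate:
                    at = _gate_t(at, lp["ga_W"], lp["ga_b"])
                parts.append(at)
            out = h_in
            for p in parts:
                out = out + p
            new_H[t] = out
        H = new_H
        if training and params.dropout > 0.0 and li < len(tp.layers) - 1:
            keep = 1.0 - params.dropout
            for t in NODE_TYPES:
                mask = (rng.random(H[t].shape) < keep) / keep
                H[t] = H[t] * Tensor(mask)
    return H["event"], H["disease"]


def encode(graph: HeteroGraph, features: FeaturePack, params: EncoderParams, seed: int = 0,
           training: bool = False, mp_edges=None) -> EmbeddingTable:
    """Run the encoder and return numpy embeddings for both node types.

    `mp_edges` restricts message passing (e.g. to training positives); by
    default all graph edges are used.
    """
    if params.n_layers < 1:
        raise ValueError("encoder needs at least one layer")
    edges = graph.edges if mp_edges is None else tuple(mp_edges)
    adj = adjacency_matrix(graph.n_events, graph.n_diseases, edges)
    tp = params_to_tensors(params, requires_grad=False)
    rng = np.random.default_rng(seed)
    He, Hd = forward_embeddings(tp, params, features, adj, rng, training=training)
    return EmbeddingTable(event=He.data.copy(), disease=Hd.data.copy())
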