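"""Edge scoring, loss, and the optimization loop.

The decoder scores an event-disease pair by aggregating the elementwise
product of the two embeddings over the embedding dimension (a dot product);
two ablation decoders (single-linear on the concatenated pair, bilinear
u^T B v) are also provided.  Training minimizes class-weighted binary
cross-entropy over positive edges plus sampled negatives with Adam, keeping
the parameters with the best validation AUC.  Message passing in every epoch
uses training positives only, so held-out edges never leak into the
adjacency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import evaluation
from .autodiff import Adam, Tensor, concat, glorot
from .encoder import (EmbeddingTable, EncoderParams, FeaturePack, adjacency_matrix,
                      encode, forward_embeddings, init_encoder_params,
                      params_to_tensors, tensors_to_params, _transpose)
from .graph import EdgeSplit, HeteroGraph, sample_negative_edges

DECODERS = ("product", "single_linear", "bilinear")


@dataclass
class Hyperparams:
    """Optimization settings (defaults follow the tuned configuration)."""

    lr: float = 1e-3
    batch_size: int = 3840
    embedding_dim: int = 64
    dropout: float = 0.6
    weight_decay: float = 1e-5
    epochs: int = 200
    seed: int = 0
    negative_ratio: float = 1.0
    positive_class_weight: float = 1.0

    def validate(self) -> None:
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        for name in ("lr", "batch_size", "embedding_dim", "epochs",
                     "negative_ratio", "positive_class_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ModelConfig:
    """Structural choices of encoder and decoder (the ablation surface)."""

    n_layers: int = 2
    k_neighbors: int = 10
    aggregator: str = "mean"
    use_conv: bool = True
    use_attention: bool = True
    use_gate: bool = True
    decoder: str = "product"
    event_embed_dim: int | None = None    # None -> embedding_dim
    leaky_slope: float = 0.2
    resample_negatives: bool = False      # per-epoch training negatives
    features_from: str = "all"            # "all" (one-hot over every link) or "train"

    def validate(self) -> None:
        if self.decoder not in DECODERS:
            raise ValueError(f"decoder must be one of {DECODERS}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")


@dataclass
class DecoderParams:
    kind: str = "product"
    w: np.ndarray | None = None     # single_linear: (2d,) weight
    b: float = 0.0                  # single_linear bias
    B: np.ndarray | None = None     # bilinear: (d, d)


@dataclass
class TrainedModel:
    encoder: EncoderParams
    decoder: DecoderParams
    config: ModelConfig
    hyperparams: Hyperparams
    mp_edges: tuple[tuple[int, int], ...] = ()   # adjacency actually used in training


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)
    val_metrics: list["evaluation.MetricsReport"] = field(default_factory=list)
    best_epoch: int = -1
    mp_edges: frozenset = frozenset()


# ---------------------------------------------------------------------------
# scoring


def score_edges(embeddings: EmbeddingTable, edges) -> np.ndarray:
    """Dot-product logits: sum over the embedding dimension of e_u * d_v."""
    edges = list(edges)
    if not edges:
        return np.zeros(0)
    us = np.array([e[0] for e in edges])
    vs = np.array([e[1] for e in edges])
    if us.max(initial=-1) >= embeddings.event.shape[0] or vs.max(initial=-1) >= embeddings.disease.shape[0]:
        raise IndexError("edge endpoint outside the embedding tables")
    return np.einsum("ij,ij->i", embeddings.event[us], embeddings.disease[vs])


def score_edges_with_decoder(embeddings: EmbeddingTable, edges, dec: DecoderParams) -> np.ndarray:
    edges = list(edges)
    if not edges:
        return np.zeros(0)
    us = np.array([e[0] for e in edges])
    vs = np.array([e[1] for e in edges])
    E, D = embeddings.event[us], embeddings.disease[vs]
    if dec.kind == "product":
        return np.einsum("ij,ij->i", E, D)
    if dec.kind == "single_linear":
        return np.concatenate([E, D], axis=1) @ dec.w + dec.b
    if dec.kind == "bilinear":
        return np.einsum("ij,ij->i", E @ dec.B, D)
    raise ValueError(f"unknown decoder {dec.kind!r}")


def edge_probability(logit):
    """Stable sigmoid mapping a logit to an existence probability in (0, 1)."""
    x = np.asarray(logit, dtype=np.float64)
    out = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                   np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x))))
    return float(out) if np.isscalar(logit) or out.ndim == 0 else out


def bce_with_logits(logits, labels, positive_class_weight: float = 1.0) -> float:
    """Class-weighted binary cross-entropy in overflow-free log-sum-exp form."""
    x = np.asarray(logits, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("logits and labels must have equal length")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    softplus = lambda t: np.maximum(t, 0.0) + np.log1p(np.exp(-np.abs(t)))
    per = positive_class_weight * y * softplus(-x) + (1.0 - y) * softplus(x)
    return float(per.mean())


# ---------------------------------------------------------------------------
# training


def _init_decoder(kind: str, d: int, rng: np.random.Generator) -> DecoderParams:
    if kind == "product":
        return DecoderParams("product")
    if kind == "single_linear":
        return DecoderParams("single_linear", w=glorot(rng, (2 * d,)), b=0.0)
    return DecoderParams("bilinear", B=glorot(rng, (d, d)))


def _decoder_tensors(dec: DecoderParams) -> dict[str, Tensor]:
    out = {}
    if dec.kind == "single_linear":
        out["w"] = Tensor(dec.w, requires_grad=True)
        out["b"] = Tensor(np.array(dec.b), requires_grad=True)
    elif dec.kind == "bilinear":
        out["B"] = Tensor(dec.B, requires_grad=True)
    return out


def _score_tensor(He: Tensor, Hd: Tensor, us, vs, dec_kind: str, dt: dict) -> Tensor:
    E, D = He.take_rows(us), Hd.take_rows(vs)
    if dec_kind == "product":
        return (E * D).sum(axis=1)
    if dec_kind == "single_linear":
        return concat([E, D], axis=1) @ dt["w"] + dt["b"]
    return ((E @ _transpose(dt["B"])) * D).sum(axis=1)


def _loss_tensor(logits: Tensor, y: np.ndarray, w_pos: float) -> Tensor:
    yt, cw = Tensor(y), Tensor(1.0 - y)
    return ((w_pos * yt) * (-logits).softplus() + cw * logits.softplus()).mean()


def train(graph: HeteroGraph, features: FeaturePack, split: EdgeSplit,
          hyperparams: Hyperparams | None = None,
          config: ModelConfig | None = None,
          permute_train_labels: bool = False) -> tuple[TrainedModel, TrainHistory]:
    """Fit the encoder/decoder on the training split.

    Per epoch: full-graph encode over the training-edge adjacency, logits for
    training positives and negatives, weighted BCE, Adam step; validation
    metrics are computed every epoch and the best-validation-AUC parameters
    are returned.  Deterministic under ``hyperparams.seed``.

    ``permute_train_labels`` shuffles the training labels once (a null-signal
    control: a sound pipeline must then score held-out edges at chance).
    """
    hp = hyperparams or Hyperparams()
    cfg = config or ModelConfig()
    hp.validate()
    cfg.validate()
    if not split.train_pos:
        raise ValueError("empty training split")

    train_pos = tuple(split.train_pos)
    mp_adj = adjacency_matrix(graph.n_events, graph.n_diseases, train_pos)

    feats = features
    if cfg.features_from == "train":
        A = adjacency_matrix(graph.n_events, graph.n_diseases, train_pos)
        feats = FeaturePack(event_onehot=A, disease=features.disease)

    d = hp.embedding_dim
    enc = init_encoder_params(
        graph.n_events, feats.event_onehot.shape[1], feats.disease.shape[1],
        d=d, n_layers=cfg.n_layers, event_embed_dim=cfg.event_embed_dim, seed=hp.seed,
        k=cfg.k_neighbors, dropout=hp.dropout, aggregator=cfg.aggregator,
        leaky_slope=cfg.leaky_slope, use_conv=cfg.use_conv,
        use_attention=cfg.use_attention, use_gate=cfg.use_gate)
    rng_init = np.random.default_rng([hp.seed, 7])
    dec = _init_decoder(cfg.decoder, d, rng_init)

    tp = params_to_tensors(enc, requires_grad=True)
    dt = _decoder_tensors(dec)
    opt = Adam(tp.all_tensors() + list(dt.values()), lr=hp.lr, weight_decay=hp.weight_decay)

    train_neg = tuple(split.train_neg)
    if not train_neg and not cfg.resample_negatives:
        train_neg = sample_negative_edges(
            graph, int(round(hp.negative_ratio * len(train_pos))), hp.seed + 101)
    val_pos, val_neg = tuple(split.val_pos), tuple(split.val_neg)

    history = TrainHistory(mp_edges=frozenset(train_pos))
    best_auc, best_state = -np.inf, None
    eval_seed = [hp.seed, 999_983]
    perm_rng = np.random.default_rng([hp.seed, 5]) if permute_train_labels else None

    def _epoch_edges(epoch: int):
        neg = train_neg
        if cfg.resample_negatives:
            neg = sample_negative_edges(
                graph, int(round(hp.negative_ratio * len(train_pos))), hp.seed + 1000 + epoch)
        e = list(train_pos) + list(neg)
        y = np.concatenate([np.ones(len(train_pos)), np.zeros(len(neg))])
        if perm_rng is not None:
            y = perm_rng.permutation(y)
        return e, y

    fixed = None if cfg.resample_negatives else _epoch_edges(0)
    for epoch in range(hp.epochs):
        edges, y_all = fixed if fixed is not None else _epoch_edges(epoch)
        order = np.random.default_rng([hp.seed, 2, epoch]).permutation(len(edges))
        us_all = np.array([edges[i][0] for i in order])
        vs_all = np.array([edges[i][1] for i in order])
        y_all = y_all[order]

        rng_fwd = np.random.default_rng([hp.seed, 3, epoch])
        epoch_loss, n_seen = 0.0, 0
        for start in range(0, len(edges), hp.batch_size):
            sl = slice(start, start + hp.batch_size)
            opt.zero_grad()
            He, Hd = forward_embeddings(tp, enc, feats, mp_adj, rng_fwd, training=True)
            logits = _score_tensor(He, Hd, us_all[sl], vs_all[sl], cfg.decoder, dt)
            loss = _loss_tensor(logits, y_all[sl], hp.positive_class_weight)
            loss.backward()
            opt.step()
            nb = len(y_all[sl])
            epoch_loss += float(loss.data) * nb
            n_seen += nb
        history.loss.append(epoch_loss / n_seen)

        # validation under eval mode (no dropout, fixed sampling seed)
        cur_enc = tensors_to_params(tp, enc)
        cur_dec = _extract_decoder(dec, dt)
        if val_pos and val_neg:
            emb = encode(graph, feats, cur_enc, seed=np.random.default_rng(eval_seed).integers(2**31),
                         mp_edges=train_pos)
            scores = score_edges_with_decoder(emb, list(val_pos) + list(val_neg), cur_dec)
            labels = np.concatenate([np.ones(len(val_pos)), np.zeros(len(val_neg))])
            report = evaluation.evaluate_scores(labels, edge_probability(scores))
            history.val_metrics.append(report)
            if report.auc > best_auc:
                best_auc, best_state = report.auc, (cur_enc, cur_dec)
                history.best_epoch = epoch
        else:
            best_state, history.best_epoch = (cur_enc, cur_dec), epoch

    enc_out, dec_out = best_state
    model = TrainedModel(encoder=enc_out, decoder=dec_out, config=cfg,
                         hyperparams=hp, mp_edges=train_pos)
    return model, history


def _extract_decoder(dec: DecoderParams, dt: dict) -> DecoderParams:
    if dec.kind == "single_linear":
        return DecoderParams("single_linear", w=dt["w"].data.copy(), b=float(dt["b"].data))
    if dec.kind == "bilinear":
        return DecoderParams("bilinear", B=dt["B"].data.copy())
    return DecoderParams("product")


def model_embeddings(model: TrainedModel, graph: HeteroGraph, features: FeaturePack,
                     seed: int | None = None) -> EmbeddingTable:
    """Eval-mode embeddings using the adjacency the model was trained on."""
    feats = features
    if model.config.features_from == "train":
        A = adjacency_matrix(graph.n_events, graph.n_diseases, model.mp_edges)
        feats = FeaturePack(event_onehot=A, disease=features.disease)
    seed = model.hyperparams.seed if seed is None else seed
    eval_seed = int(np.random.default_rng([seed, 999_983]).integers(2**31))
    return encode(graph, feats, model.encoder, seed=eval_seed, mp_edges=model.mp_edges)


def predict_links(model: TrainedModel, graph: HeteroGraph, features: FeaturePack,
                  event_index: int, threshold: float = 0.5) -> list[tuple[int, float]]:
    """Probabilities of event_index against every disease, filtered and ranked.

    Returns (disease_index, probability) pairs with probability >= threshold,
    sorted by descending probability (ties broken by disease index).
    """
    if not 0 <= event_index < graph.n_events:
        raise IndexError(f"unknown event {event_index}")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    emb = model_embeddings(model, graph, features)
    edges = [(event_index, j) for j in range(graph.n_diseases)]
    probs = edge_probability(score_edges_with_decoder(emb, edges, model.decoder))
    ranked = sorted(((j, float(p)) for j, p in enumerate(probs) if p >= threshold),
                    key=lambda t: (-t[1], t[0]))
    return ranked


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: TrainedModel, path: str | Path) -> None:
    """Named-array archive plus a JSON sidecar of hyperparameters/config."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for t, m in model.encoder.M.items():
        arrays[f"M_{t}"] = m
    if model.encoder.event_embed is not None:
        arrays["event_embed"] = model.encoder.event_embed
    for i, l in enumerate(model.encoder.layers):
        arrays[f"l{i}_W"] = l.W
        arrays[f"l{i}_U"] = l.U
        for t in l.W_att:
            arrays[f"l{i}_Watt_{t}"] = l.W_att[t]
            arrays[f"l{i}_a_{t}"] = l.a[t]
        arrays[f"l{i}_gcW"] = l.gate_conv_W
        arrays[f"l{i}_gcb"] = l.gate_conv_b
        arrays[f"l{i}_gaW"] = l.gate_att_W
        arrays[f"l{i}_gab"] = l.gate_att_b
    if model.decoder.w is not None:
        arrays["dec_w"] = model.decoder.w
        arrays["dec_b"] = np.array(model.decoder.b)
    if model.decoder.B is not None:
        arrays["dec_B"] = model.decoder.B
    arrays["mp_edges"] = np.array(model.mp_edges, dtype=np.int64).reshape(-1, 2)
    base = str(path).removesuffix(".npz")
    np.savez(base + ".npz", **arrays)
    sidecar = {"hyperparams": asdict(model.hyperparams), "config": asdict(model.config),
               "decoder_kind": model.decoder.kind}
    Path(base + ".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def load_checkpoint(path: str | Path) -> TrainedModel:
    base = str(path).removesuffix(".json").removesuffix(".npz")
    data = np.load(base + ".npz")
    sidecar = json.loads(Path(base + ".json").read_text())
    hp = Hyperparams(**sidecar["hyperparams"])
    cfg = ModelConfig(**sidecar["config"])
    from .encoder import LayerParams
    n_layers = cfg.n_layers
    layers = [LayerParams(
        W=data[f"l{i}_W"],
        W_att={t: data[f"l{i}_Watt_{t}"] for t in ("event", "disease")},
        a={t: data[f"l{i}_a_{t}"] for t in ("event", "disease")},
        U=data[f"l{i}_U"],
        gate_conv_W=data[f"l{i}_gcW"], gate_conv_b=data[f"l{i}_gcb"],
        gate_att_W=data[f"l{i}_gaW"], gate_att_b=data[f"l{i}_gab"],
    ) for i in range(n_layers)]
    enc = EncoderParams(
        M={"event": data["M_event"], "disease": data["M_disease"]},
        layers=layers,
        event_embed=data["event_embed"] if "event_embed" in data else None,
        d=hp.embedding_dim, k=cfg.k_neighbors, dropout=hp.dropout,
        aggregator=cfg.aggregator, leaky_slope=cfg.leaky_slope,
        use_conv=cfg.use_conv, use_attention=cfg.use_attention, use_gate=cfg.use_gate)
    kind = sidecar["decoder_kind"]
    dec = DecoderParams(kind,
                        w=data["dec_w"] if "dec_w" in data else None,
                        b=float(data["dec_b"]) if "dec_b" in data else 0.0,
                        B=data["dec_B"] if "dec_B" in data else None)
    mp_edges = tuple(map(tuple, data["mp_edges"].tolist()))
    return TrainedModel(encoder=enc, decoder=dec, config=cfg, hyperparams=hp, mp_edges=mp_edges)
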