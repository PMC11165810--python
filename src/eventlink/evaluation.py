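"""Binary link-prediction metrics, curve export and the ablation harness.

Six values summarize every evaluation: AUC (Mann-Whitney, midrank ties),
Accuracy, F1, Precision, Recall, and AUPR (step-wise average precision).
Threshold-based counts use the ``probability >= threshold`` rule with a 0.5
default.  Zero-denominator precision/recall/F1 return 0 rather than NaN so
ablation tables never contain undefined cells.

ROC/PR computation is delegated to scikit-learn; the test suite cross-checks
it against exhaustive pairwise concordance and hand-stepped curves.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from sklearn import metrics as _skm

METRIC_NAMES = ("auc", "accuracy", "f1", "precision", "recall", "aupr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    auc: float
    accuracy: float
    f1: float
    precision: float
    recall: float
    aupr: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)

    def as_row(self) -> list[float]:
        return [getattr(self, m) for m in METRIC_NAMES]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.float64)
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    return labels


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Tally TP/FP/FN/TN with predictions positive iff probability >= threshold."""
    labels = _check_binary(labels)
    probs = np.asarray(probabilities, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    if labels.shape != probs.shape:
        raise ValueError("labels and probabilities must have equal length")
    pred = probs >= threshold
    pos = labels == 1.0
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)), fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)), tn=int(np.sum(~pred & ~pos)))


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else 0.0


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0


def recall(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    return 2.0 * p * r / (p + r) if (p + r) else 0.0


def roc_auc(labels, scores) -> float:
    """Probability a random positive outscores a random negative (ties count 1/2)."""
    labels = _check_binary(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(_skm.roc_auc_score(labels, scores))


def roc_curve_points(labels, scores) -> np.ndarray:
    """(FPR, TPR) curve points, FPR = FP/(FP+TN), TPR = TP/(TP+FN)."""
    fpr, tpr, _ = _skm.roc_curve(_check_binary(labels), scores)
    return np.column_stack([fpr, tpr])


def pr_auc(labels, scores) -> float:
    """Area under the precision-recall step curve (average precision)."""
    labels = _check_binary(labels)
    if labels.sum() == 0:
        raise ValueError("AUPR undefined without positive samples")
    return float(_skm.average_precision_score(labels, scores))


def pr_curve_points(labels, scores) -> np.ndarray:
    prec, rec, _ = _skm.precision_recall_curve(_check_binary(labels), scores)
    return np.column_stack([rec, prec])


def evaluate_scores(labels, probabilities, threshold: float = 0.5) -> MetricsReport:
    """All six metrics from labels and predicted probabilities."""
    c = confusion(labels, probabilities, threshold)
    return MetricsReport(
        auc=roc_auc(labels, probabilities),
        accuracy=accuracy(c), f1=f1(c), precision=precision(c), recall=recall(c),
        aupr=pr_auc(labels, probabilities))


def evaluate(model, graph, features, pos_edges, neg_edges,
             threshold: float = 0.5) -> MetricsReport:
    """Score pos/neg edge sets with a trained model and report all six metrics."""
    from .training import edge_probability, model_embeddings, score_edges_with_decoder

    pos_edges, neg_edges = list(pos_edges), list(neg_edges)
    if not pos_edges or not neg_edges:
        raise ValueError("evaluation needs non-empty positive and negative edge sets")
    emb = model_embeddings(model, graph, features)
    logits = score_edges_with_decoder(emb, pos_edges + neg_edges, model.decoder)
    labels = np.concatenate([np.ones(len(pos_edges)), np.zeros(len(neg_edges))])
    return evaluate_scores(labels, edge_probability(logits), threshold)


def write_curves(labels, scores, outdir, stem: str = "model") -> None:
    """Export ROC and PR curve points as CSV (and a PNG if matplotlib imports)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    np.savetxt(outdir / f"{stem}_roc.csv", roc_curve_points(labels, scores),
               delimiter=",", header="fpr,tpr", comments="")
    np.savetxt(outdir / f"{stem}_pr.csv", pr_curve_points(labels, scores),
               delimiter=",", header="recall,precision", comments="")
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception:   # plotting is best-effort
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    roc = roc_curve_points(labels, scores)
    pr = pr_curve_points(labels, scores)
    axes[0].plot(roc[:, 0], roc[:, 1])
    axes[0].set(xlabel="FPR", ylabel="TPR", title=f"ROC (AUC={roc_auc(labels, scores):.5f})")
    axes[1].plot(pr[:, 0], pr[:, 1])
    axes[1].set(xlabel="Recall", ylabel="Precision",
                title=f"PR (AUPR={pr_auc(labels, scores):.5f})")
    fig.tight_layout()
    fig.savefig(outdir / f"{stem}_curves.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# ablation harness


#: Structural variants: layer-count sweep, single-branch encoders, gate removal,
#: and the three decoders.  ``two_layer`` + ``decoder_product`` is the default model.
ABLATION_VARIANTS: dict[str, dict] = {
    "one_layer": {"n_layers": 1},
    "two_layer": {"n_layers": 2},
    "three_layer": {"n_layers": 3},
    "conv_only": {"use_attention": False},
    "attention_only": {"use_conv": False},
    "no_gate": {"use_gate": False},
    "decoder_product": {"decoder": "product"},
    "decoder_single_linear": {"decoder": "single_linear"},
    "decoder_bilinear": {"decoder": "bilinear"},
}


def variant_config(name: str, base=None):
    from dataclasses import replace

    from .training import ModelConfig

    if name not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown variant {name!r}; valid names: {sorted(ABLATION_VARIANTS)}")
    return replace(base or ModelConfig(), **ABLATION_VARIANTS[name])


def run_ablation(graph, features, split, variants=None, seeds=(0,),
                 hyperparams=None, base_config=None):
    """Train and evaluate every named variant per seed; mean metrics per variant.

    Returns a pandas DataFrame (variant x six metrics, averaged over seeds).
    """
    import pandas as pd
    from dataclasses import replace

    from .training import Hyperparams, train

    names = list(variants) if variants is not None else list(ABLATION_VARIANTS)
    hp = hyperparams or Hyperparams()
    rows = {}
    for name in names:
        cfg = variant_config(name, base_config)
        reports = []
        for seed in seeds:
            model, _ = train(graph, features, split, replace(hp, seed=int(seed)), cfg)
            reports.append(evaluate(model, graph, features, split.test_pos, split.test_neg))
        rows[name] = np.mean([r.as_row() for r in reports], axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(METRIC_NAMES)).loc[names]


def write_ablation_table(table, path) -> None:
    """Five-decimal TSV, one row per variant, six metric columns."""
    table.round(5).to_csv(path, sep="\t", index_label="variant", float_format="%.5f")
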