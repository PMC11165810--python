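"""End-to-end pipeline functions: simulate, build, train, evaluate, predict, export.

These are the scriptable entry points tying the library together (the
``examples/`` directory shows each one in a short narrative form).  Every
function is deterministic under a fixed :class:`RunConfig` and writes a
provenance JSON (config hash, seed, versions) next to its outputs so a result
can always be traced back to the exact configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .encoder import FeaturePack
from .evaluation import MetricsReport, run_ablation, write_ablation_table
from .graph import (EdgeSplit, EntityVocab, HeteroGraph, attach_negatives,
                    build_event_features, build_events, build_hetero_graph,
                    init_disease_features, load_pair_tables, save_graph, split_edges,
                    vocab_from_tables)
from .synthetic import SyntheticConfig, generate, write_cluster_sidecar
from .training import (Hyperparams, ModelConfig, TrainedModel, predict_links,
                       save_checkpoint, train)
from . import evaluation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one run needs: data source, hyperparameters, split, seed, outputs."""

    table_paths: tuple[str, str, str] | None = None     # drug-target, drug-disease, target-disease
    synthetic: SyntheticConfig | None = None
    hyperparams: Hyperparams = field(default_factory=Hyperparams)
    model: ModelConfig = field(default_factory=ModelConfig)
    ratios: tuple[float, float, float] = (0.6, 0.1, 0.3)
    disease_feature_dim: int = 64
    seed: int = 0
    outdir: str = "runs/default"

    def validate(self) -> None:
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if (self.table_paths is None) == (self.synthetic is None):
            raise ValueError("exactly one of table_paths / synthetic must be set")

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            d["synthetic"] = SyntheticConfig(**d["synthetic"])
        if d.get("table_paths") is not None:
            d["table_paths"] = tuple(d["table_paths"])
        d["hyperparams"] = Hyperparams(**d.get("hyperparams", {}))
        d["model"] = ModelConfig(**d.get("model", {}))
        d["ratios"] = tuple(d.get("ratios", (0.6, 0.1, 0.3)))
        return RunConfig(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        return RunConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_provenance(config: RunConfig, outdir: Path) -> None:
    prov = {"config_hash": config_hash(config), "seed": config.seed,
            "eventlink_version": __version__, "numpy_version": np.__version__}
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages


@dataclass
class GraphArtifacts:
    vocab: EntityVocab
    events: list
    graph: HeteroGraph
    features: FeaturePack
    summary: dict


def simulate(config: RunConfig, write: bool = True):
    """Draw synthetic pair tables (and ground-truth clusters) per the config."""
    config.validate()
    if config.synthetic is None:
        raise ValueError("simulate requires a synthetic config")
    dt, dd, td, clusters = generate(config.synthetic)
    if write:
        from .graph import write_pair_table

        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_pair_table(dt, outdir / "drug_target.tsv")
        write_pair_table(dd, outdir / "drug_disease.tsv")
        write_pair_table(td, outdir / "target_disease.tsv")
        write_cluster_sidecar(clusters, outdir / "clusters.tsv")
        write_provenance(config, outdir)
    return dt, dd, td, clusters


def build_graph(config: RunConfig, write: bool = True) -> GraphArtifacts:
    """Tables -> vocabulary -> events -> heterograph -> features, with a count summary."""
    config.validate()
    if config.table_paths is not None:
        vocab, dt, dd, td = load_pair_tables(*config.table_paths)
    else:
        dt, dd, td, _ = simulate(config, write=False)
        vocab = vocab_from_tables(dt, dd, td)
    events = build_events(dt, dd, td, vocab)
    graph = build_hetero_graph(events, vocab.n_diseases)
    features = FeaturePack(
        event_onehot=build_event_features(events, vocab.n_diseases),
        disease=init_disease_features(vocab.n_diseases, config.disease_feature_dim, config.seed),
    )
    outdir = Path(config.outdir)
    if write:
        summary = save_graph(graph, events, vocab, outdir)
        write_provenance(config, outdir)
    else:
        summary = {"n_drugs": vocab.n_drugs, "n_targets": vocab.n_targets,
                   "n_diseases": vocab.n_diseases, "n_events": graph.n_events,
                   "n_edges": len(graph.edges)}
    logger.info("graph summary: %s", summary)
    return GraphArtifacts(vocab, events, graph, features, summary)


def make_split(config: RunConfig, graph: HeteroGraph) -> EdgeSplit:
    split = split_edges(graph, config.ratios, seed=config.seed)
    return attach_negatives(graph, split, ratio=config.hyperparams.negative_ratio,
                            seed=config.seed + 17)


def train_model(config: RunConfig, artifacts: GraphArtifacts | None = None,
                write: bool = True):
    """Split, train, checkpoint; returns (model, history, split, artifacts)."""
    config.validate()
    art = artifacts or build_graph(config, write=write)
    split = make_split(config, art.graph)
    model, history = train(art.graph, art.features, split, config.hyperparams, config.model)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(model, outdir / "checkpoint.npz")
        hist = {"loss": history.loss,
                "val_auc": [m.auc for m in history.val_metrics],
                "best_epoch": history.best_epoch}
        (outdir / "history.json").write_text(json.dumps(hist, indent=2, sort_keys=True) + "\n")
        write_provenance(config, outdir)
    return model, history, split, art


def evaluate_model(config: RunConfig, model: TrainedModel, art: GraphArtifacts,
                   split: EdgeSplit, write: bool = True) -> MetricsReport:
    """Test-set metrics; writes metrics.json/.tsv when asked."""
    report = evaluation.evaluate(model, art.graph, art.features,
                                 split.test_pos, split.test_neg)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rounded = {k: round(v, 5) for k, v in report.as_dict().items()}
        (outdir / "metrics.json").write_text(json.dumps(rounded, indent=2, sort_keys=True) + "\n")
        with (outdir / "metrics.tsv").open("w") as fh:
            fh.write("\t".join(evaluation.METRIC_NAMES) + "\n")
            fh.write("\t".join(f"{v:.5f}" for v in report.as_row()) + "\n")
    return report


def ablate(config: RunConfig, seeds=(0, 1, 2), variants=None, write: bool = True):
    """Run the variant registry on the configured data; emits a TSV table."""
    art = build_graph(config, write=False)
    split = make_split(config, art.graph)
    table = run_ablation(art.graph, art.features, split, variants=variants,
                         seeds=seeds, hyperparams=config.hyperparams,
                         base_config=config.model)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ablation_table(table, outdir / "ablation.tsv")
        write_provenance(config, outdir)
    return table


def predict(config: RunConfig, model: TrainedModel, art: GraphArtifacts,
            event_index: int, threshold: float = 0.5, write: bool = True):
    """Ranked disease predictions for one event, written as TSV."""
    ranked = predict_links(model, art.graph, art.features, event_index, threshold)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with (outdir / f"predictions_event{event_index}.tsv").open("w") as fh:
            fh.write("event_id\tdisease_id\tprobability\trank\n")
            for rank, (j, p) in enumerate(ranked, start=1):
                fh.write(f"{event_index}\t{art.vocab.disease_ids[j]}\t{p:.6f}\t{rank}\n")
    return ranked


def export_prediction_graph(model: TrainedModel, art: GraphArtifacts, split: EdgeSplit,
                            n_edges: int = 100, threshold: float = 0.5,
                            path=None) -> list[tuple[int, int, str]]:
    """Edge list with status labels for visualization.

    Statuses partition the emitted edges: ``test-correct`` (held-out edge the
    model recovers at the threshold), ``test-missed`` (held-out edge it does
    not), and ``train`` (edge seen during training).  Test edges are emitted
    first, then training edges, up to ``n_edges`` rows.
    """
    from .training import edge_probability, model_embeddings, score_edges_with_decoder

    if n_edges <= 0:
        raise ValueError("n_edges must be positive")
    emb = model_embeddings(model, art.graph, art.features)
    test = list(split.test_pos)
    rows: list[tuple[int, int, str]] = []
    if test:
        probs = edge_probability(score_edges_with_decoder(emb, test, model.decoder))
        for (u, v), p in zip(test, probs):
            rows.append((u, v, "test-correct" if p >= threshold else "test-missed"))
    rows.extend((u, v, "train") for u, v in split.train_pos)
    rows = rows[:n_edges]
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with Path(path).open("w") as fh:
            fh.write("event_id\tdisease_id\tstatus\n")
            for u, v, s in rows:
                fh.write(f"{u}\t{v}\t{s}\n")
    return rows
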