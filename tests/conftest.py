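import numpy as np
import pytest

import eventlink as el
from eventlink.pipeline import RunConfig, build_graph, make_split
from eventlink.training import Hyperparams, train


@pytest.fixture(scope="session")
def fixture_tables():
    """Tiny deterministic 3-drug/3-target/6-disease dataset."""
    return el.make_fixture()


@pytest.fixture(scope="session")
def fixture_graph(fixture_tables):
    vocab, dt, dd, td = fixture_tables
    events = el.build_events(dt, dd, td, vocab)
    graph = el.build_hetero_graph(events, vocab.n_diseases)
    return vocab, events, graph


@pytest.fixture(scope="session")
def small_run_config():
    """Small planted-cluster benchmark used for training-level tests."""
    return RunConfig(
        synthetic=el.SyntheticConfig(n_drugs=30, n_targets=20, n_diseases=60,
                                     n_clusters=3, seed=5),
        hyperparams=Hyperparams(embedding_dim=16, epochs=30, seed=1),
        disease_feature_dim=16, seed=1, outdir="scratch/test-run")


@pytest.fixture(scope="session")
def small_artifacts(small_run_config):
    art = build_graph(small_run_config, write=False)
    split = make_split(small_run_config, art.graph)
    return art, split


@pytest.fixture(scope="session")
def small_trained(small_run_config, small_artifacts):
    art, split = small_artifacts
    model, history = train(art.graph, art.features, split,
                           small_run_config.hyperparams, small_run_config.model)
    return model, history


def random_graph(rng, n_events=8, n_diseases=10, p=0.35):
    """Random bipartite event-disease graph with annotations (test helper)."""
    edges = [(u, v) for u in range(n_events) for v in range(n_diseases)
             if rng.random() < p]
    if not edges:
        edges = [(0, 0)]
    ann = tuple((u % 3, u % 2) for u in range(n_events))
    return el.HeteroGraph(n_events, n_diseases, tuple(sorted(edges)), ann)
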