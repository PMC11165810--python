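"""Rank candidate diseases for one event and export a visualization edge list.

After training, every event can be scored against all diseases; links above a
probability threshold are candidate new indications for that drug-target pair.
"""

import eventlink as el
from eventlink.pipeline import (RunConfig, build_graph, export_prediction_graph,
                                make_split)
from eventlink.training import Hyperparams, train

cfg = RunConfig(
    synthetic=el.SyntheticConfig(n_drugs=30, n_targets=20, n_diseases=60,
                                 n_clusters=3, seed=5),
    hyperparams=Hyperparams(embedding_dim=32, epochs=200, seed=1),
    disease_feature_dim=32, seed=1, outdir="scratch/example-predict")

art = build_graph(cfg, write=False)
split = make_split(cfg, art.graph)
model, _ = train(art.graph, art.features, split, cfg.hyperparams, cfg.model)

event = 0
drug, target = art.graph.event_annotations[event]
print(f"event {event} = <{art.vocab.drug_ids[drug]}, {art.vocab.target_ids[target]}>")
ranked = el.predict_links(model, art.graph, art.features, event, threshold=0.5)
known = {v for u, v in art.graph.edges if u == event}
print(f"{len(ranked)} diseases above probability 0.5 (top 5):")
for j, p in ranked[:5]:
    tag = "known" if j in known else "novel candidate"
    print(f"  {art.vocab.disease_ids[j]}  p={p:.4f}  ({tag})")

rows = export_prediction_graph(model, art, split, n_edges=100,
                               path="scratch/example-predict/viz.tsv")
counts = {s: sum(1 for r in rows if r[2] == s) for s in
          ("train", "test-correct", "test-missed")}
print(f"visualization edge list (100 rows): {counts}")
# 'novel candidate' rows are links absent from the input graph that the model
# scores as likely -- the drug-repurposing hypotheses this pipeline produces.
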