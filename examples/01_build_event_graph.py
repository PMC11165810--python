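"""Derive event nodes and the event-disease graph from three pair tables.

An *event* is a drug-target pair together with the set of diseases both the
drug and the target are associated with; each event becomes one node linked
to every disease in its set.
"""

import eventlink as el

vocab, dt, dd, td = el.make_fixture()      # 3 drugs, 3 targets, 6 diseases
events = el.build_events(dt, dd, td, vocab)
graph = el.build_hetero_graph(events, vocab.n_diseases)

print(f"{len(events)} events from {len(dt.rows)} drug-target pairs")
for ev in events:
    drug = vocab.drug_ids[ev.drug_index]
    target = vocab.target_ids[ev.target_index]
    zs = sorted(vocab.disease_ids[z] for z in ev.diseases)
    print(f"  <{drug}, {target}> treats {zs}")
print(f"heterogeneous graph: {graph.n_events} event nodes, "
      f"{graph.n_diseases} disease nodes, {len(graph.edges)} links")
# Each printed event collapses one drug-target pair and its treatable diseases
# into a single node; the link count is the sum of the disease-set sizes.
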