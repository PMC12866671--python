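"""Attribute one predicted association to features, edges and meta-paths.

Trains a small model, explains its most confident held-out positive pair by
integrated gradients (features against a zero baseline; every edge through a
continuous presence mask), prints the contribution shares per node type and
relation, and enumerates the strongest ncRNA->drug meta-paths inside the
top-attribution subnetwork.
"""

import numpy as np

from ncdres import (
    SynthConfig,
    TrainConfig,
    attribute_prediction,
    dataset_from_network,
    enumerate_meta_paths,
    generate,
    top_k_edge_subnetwork,
    train_model,
    training_graph,
    type_contribution_shares,
)

network, _ = generate(
    SynthConfig(seed=3, n_lnc=60, n_mi=30, n_drug=10, positives_per_drug=8)
)
config = TrainConfig(epochs=30, seed=3)
dataset = dataset_from_network(network, config)
model, _ = train_model(network, dataset, config)
graph = training_graph(network, dataset, config)

candidates = dataset.positives("test")
pair = candidates[int(np.argmax(np.abs(model.predict(graph, candidates))))]
result = attribute_prediction(model, graph, pair, steps=100)

print(f"explained pair      : {pair}")
print(f"logit f(x) / f(0)   : {result.f_input:.3f} / {result.f_baseline:.3f}")
span = abs(result.f_input - result.f_baseline)
print(f"completeness gap    : {abs(result.completeness_gap) / span:.2%} of span")

shares = type_contribution_shares(result)
print("node-type shares (%):",
      {k: round(v, 1) for k, v in shares["node_types"].items()})
print("relation shares  (%):",
      {k: round(v, 1) for k, v in shares["relations"].items()})

sub, _ = top_k_edge_subnetwork(result, graph, k=300)
paths = enumerate_meta_paths(sub, pair[0], pair[1], max_len=3)
print(f"\ntop meta-paths in the 300-edge evidence subnetwork "
      f"({len(paths)} found):")
for p in paths[:5]:
    print("  " + " -> ".join(p.nodes), f"(relations {'/'.join(p.relations)}, "
          f"score {p.score:.4f})")
print(
    "\nHigh shares for the association relations and paths through shared "
    "interaction\npartners are the mechanistic reading of the prediction."
)
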