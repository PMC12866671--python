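# ncdres

Heterogeneous graph learning for predicting ncRNA–drug resistance
associations.

Non-coding RNAs — long non-coding RNAs (lncRNAs) and microRNAs (miRNAs) —
are central regulators of chemotherapeutic drug resistance, but the curated
catalogue of ncRNA–drug resistance associations is a sparse bipartite
network. `ncdres` enriches that network into a six-relation heterogeneous
graph (lncRNA/miRNA/drug similarity plus lncRNA–miRNA interactions and the
two prior association sets), learns node embeddings with relation-type-aware
message passing, scores candidate pairs with an MLP edge decoder, and
explains its predictions with gradient-based edge attribution and meta-path
extraction. It is a library for computational biologists studying drug
response, with a thin CLI for running the pipeline from the shell.

## Model

Three node types (lncRNA, miRNA, drug) carry attribute vectors: expression
profiles across cancer cell lines for ncRNAs, circular (Morgan) fingerprints
— or pluggable pretrained SMILES embeddings — for drugs. Six undirected
relations R = {ll, mm, dd, lm, ld, md} connect them: expression similarity
(Kendall tau-b > 0.5), structural similarity (Tanimoto > 0.5), curated
lncRNA–miRNA interactions, and the known lncRNA–drug / miRNA–drug resistance
associations.

Each undirected cross-type relation contributes two directed message
streams with independent weights. Per layer, for a directed relation r into
node v:

    f_r(v) = W_r^self h_v + Σ_{u ∈ N_r(v)} W_r^neigh h_u

and each node type pools its three incoming streams elementwise before the
activation:

    h_lncRNA = σ( ⊕(f_ll, f_lm, f_ld) )
    h_miRNA  = σ( ⊕(f_mm, f_ml, f_md) )
    h_drug   = σ( ⊕(f_dd, f_dl, f_dm) )

with σ = LeakyReLU and ⊕ ∈ {min, mean, sum, max} (default min). A candidate
pair (m, d) is scored by a three-layer MLP on the concatenated embeddings,

    P = W3·LeakyReLU(W2·LeakyReLU(W1·[h_m ‖ h_d] + b1) + b2) + b3,

trained full-batch with Adam on the sigmoid binary cross-entropy, with
negatives sampled at twice the positive count and a stratified 0.6/0.2/0.2
train/validation/test split. Validation and test association edges are
removed from the message-passing graph before training, so evaluation
measures generalisation to genuinely unseen pairs.

Predictions are explained by integrated gradients against a zero baseline,
with every edge carried through a continuous presence mask, yielding
per-feature and per-edge attributions whose sums reproduce the logit
difference (completeness). The top-k edges by |attribution| form an evidence
subnetwork in which ncRNA→drug meta-paths are enumerated and ranked.

The whole model — message passing, decoder, training loop, and attribution —
runs on a small numpy reverse-mode autodiff tape (`ncdres.autodiff`); there
is no deep-learning framework dependency.

## Worked example

```bash
python examples/02_train_and_evaluate.py
```

generates a planted-signal synthetic network (200 lncRNAs, 100 miRNAs, 30
drugs whose latent module structure drives features, similarity edges and
associations alike), trains for 50 epochs, and prints:

```
epochs trained      : 50
training loss       : 0.694 -> 0.136
best epoch (val AUC): 49
test AUC            : 0.945
test AUPR           : 0.934
test Precision@30   : 1.000
test NDCG@30        : 1.000
```

Test AUC ≈ 0.95 against a chance level of 0.5 (and ≈ 0.48 for a
label-shuffled control) shows the encoder/decoder recover the planted
module-affinity signal. The other examples build a network from raw tables
(`01`), attribute a prediction to edges and meta-paths (`03`), and run the
leave-one-drug-out cold-start protocol (`04`).

The same pipeline runs from the shell:

```bash
ncdres simulate --seed 1 --out runs/sim
ncdres train    --network runs/sim/network --seed 1 --out runs/train
ncdres evaluate --network runs/sim/network \
                --checkpoint runs/train/checkpoint.npz --seed 1 --out runs/eval
```

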