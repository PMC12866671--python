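# Methods

## Data model and network construction

The heterogeneous network has three node types (lncRNA, miRNA, drug) and six
undirected relations R = {ll, mm, dd, lm, ld, md}. Inputs are delimited text
tables: expression matrices (entities × cancer cell lines), a drug SMILES
table, and two-column pair lists. Identifiers are opaque case-sensitive
strings; delimiters are auto-detected between tab and comma. Expression rows
containing missing values are dropped with a logged warning rather than
imputed, mirroring how entities without usable profiles are excluded
upstream.

ncRNA similarity (ll, mm) uses Kendall's tau-b — the tie-corrected variant,
since expression data contain ties — over the cell-line profiles, computed
with `scipy.stats.kendalltau`. Drug similarity (dd) uses the Tanimoto
coefficient over circular (Morgan) fingerprints, radius 2, 2048 bits
(RDKit); both width and radius are configurable because the deposited edge
counts may be sensitive to the exact fingerprint. An edge is retained only
when the similarity is strictly greater than the threshold (default 0.5).
Pairs whose tau is undefined (zero-variance profiles) yield a NaN sentinel
and no edge. Drugs whose SMILES fail to parse are excluded from dd edges
(logged) and receive all-zero fingerprint features.

Drug attribute features default to the fingerprint matrix; a
`pretrained-embedding` mode accepts any callable mapping SMILES to vectors
(e.g. a transformer encoder) and caches its output to disk, raising a clear
error when neither an encoder nor a cache is available. Feature-dimension
mismatch across node types is absorbed by type-specific linear input
projections in the encoder, not by padding.

Two ablation switches reproduce the reduced-network baselines:
`drop_cross_ncrna` removes the non-target ncRNA type and every relation
touching it; `one_hot_attributes` replaces all attribute matrices with
one-hot identities.

## Encoder

Each undirected cross-type relation expands into two directed streams with
independent parameters (lm/ml, ld/dl, md/dm); intra-type relations use one
parameter pair applied symmetrically. The per-relation message is a plain
sum — no degree normalisation, no implicit self-loops — with a separate
self-transform:

    f_r(v) = W_r^self h_v + Σ_{u ∈ N_r(v)} W_r^neigh h_u.

Per layer, each node type pools its three incoming streams elementwise
(min/mean/sum/max; min by default) and applies LeakyReLU. Relations with no
edges contribute their self term only. Design choices left open by the
architecture: L = 2 layers, LeakyReLU negative slope 0.01, one activation
after pooling per layer with the final layer's output used directly by the
decoder, and uniform Glorot initialisation seeded from the run seed. Ties in
min/max pooling split the subgradient equally across tied streams, a
deterministic and symmetric convention.

Two execution paths exist: a per-edge scatter (sparse) path and a dense
adjacency-product reference; the test suite holds them to 1e-5 relative
agreement across all aggregation strategies, and checks permutation
equivariance of the whole forward pass.

## Decoder, objective, and training

A pair (n, d) is represented by concatenation (ncRNA block first) and scored
by a three-layer MLP with LeakyReLU activations and hidden widths (hidden,
hidden/2); the output is a raw logit. The loss is the mean sigmoid binary
cross-entropy in its log-sum-exp stabilised form. Defaults follow the tuned
configuration: learning rate 5e-4, 100 epochs (50 in the desk-scale
experiments below), hidden dimension 64, min aggregation. The optimiser is
Adam with conventional moments; weight decay and dropout are available but
default to off.

Negatives are sampled once, uniformly without replacement from the unknown
pairs at twice the positive count, and held fixed. Splitting is stratified
by label at 0.6/0.2/0.2 with floor rounding and the remainder assigned to
train; no pair appears in more than one split.

Leakage policy: the target association relation in the message-passing graph
is replaced by exactly the training-split positives before training, and the
same reduced graph is used when scoring held-out pairs (transductive node
set, inductive edges). A programmatic guard asserts the multiset equality on
every run. `exclude_eval_edges=False` restores the permissive variant for
comparison. Model selection returns the epoch with the best validation AUC
(earliest on ties).

## Evaluation

AUC is the Mann–Whitney statistic (ties counted 1/2) and AUPR the
precision–recall step-curve area, both via scikit-learn and cross-checked
against exhaustive oracles on all labelled score vectors of length ≤ 8.
Top-k metrics use binary relevance with ties broken by stable input order
(sort key: −score, then input index): Precision@k, Recall@k, and NDCG@k with
DCG = Σ rel_i / log2(i+1) normalised by the ideal ordering over the same k.
k defaults to {10, 30}.

The cold-start protocol removes every target-relation edge incident to one
held-out ncRNA or drug, retrains, and ranks the entity against all candidate
partners — its true partners as positives, all partners with no known
association to it as negatives (the candidate universe is a design choice).
Cold-start rankings are much noisier than the standard split, especially on
small networks where few same-module drugs remain to learn feature→module
generalisation from; the batch runner reports one row per entity so that
per-entity variability stays visible.

## Attribution

Integrated gradients re-implemented on the package's own autodiff tape, with
a zero baseline: node features are interpolated 0 → x and every stored
undirected edge carries a continuous mask interpolated 0 → 1 (one mask per
stored edge, shared by both directed orientations). The attribution target
is the pre-sigmoid logit, for additivity. The path integral uses a midpoint
Riemann sum (default 50 steps; 200 in the completeness checks): the
integrand is piecewise smooth with kinks from LeakyReLU and min/max pooling,
so the residual completeness gap decays with the step count and is verified
to stay within 1% of the logit span at 200 steps on trained models. Because
the gap is an absolute quantity, relative completeness is only meaningful
for pairs whose logit span is not degenerate — the checks therefore explain
the most confidently scored held-out positive, which is also how attribution
is used in practice (explaining validated or high-confidence predictions).
Type-level contribution shares aggregate |attribution| (signed tables are
also available); the top-k edge subnetwork (default k = 300) keeps the
strongest edges plus incident nodes, and meta-paths are all simple
source→target paths of ≤ 3 edges ranked by the sum of |edge attribution|
(ties lexicographic), enumerated with networkx.

## Synthetic study conditions

The generator plants a recoverable association signal in a network of 200
lncRNAs, 100 miRNAs and 30 drugs. Every node draws a nonnegative latent
loading vector over 8 factors: faint exponential background (scale 0.1) plus
one dominant factor per node (1 + Exp(0.5)) — modelling co-expression
modules for ncRNAs and mechanism classes for drugs. Observables derive from
the loadings: features are a linear map to 32 dimensions plus Gaussian noise
(σ = 0.1); similarity and lncRNA–miRNA edges connect pairs whose loadings
correlate above 0.5; true associations are, per drug, the top-10 ncRNAs by
latent inner product (a quantile cut), with 5% of labels flipped (dropped
positives and promoted unknowns). All randomness flows from one seed through
spawned, independent sub-streams.

The module-structured (rather than zero-mean Gaussian) loadings are a
deliberate design choice: they are the realistic structure of molecular
association data — hubs and community affinity — and they make the planted
signal recoverable by the concat-MLP decoder within the fixed training
budget, while the 5% label noise keeps recovery below ceiling. Under these
conditions the pipeline reaches mean held-out AUC ≈ 0.95 over 5 seeds at 50
epochs, the rewired-association control sits at chance, and removing the
lncRNA–miRNA relation does not improve performance. What the synthetic
study does *not* emulate: the real data's exact degree distributions and
edge counts, measurement-driven expression ties, batch structure, or
database curation biases — passing these tests demonstrates correct
mechanics and sensible inductive behaviour, not real-data performance.

Desk-scale problem sizes (50 epochs, 60/30/10-node networks for the
attribution and cold-start demonstrations) are the package's chosen
experiment sizes; all are configurable.

## Degenerate inputs and numerical conventions

Hard errors (never silent): duplicate identifiers, non-numeric cells,
self-pairs, malformed rows, empty target association sets, single-class
metric inputs, k outside [1, n], insufficient unknown pairs for negative
sampling, split classes too small to populate all splits, non-finite losses
or embeddings (named by layer/epoch), checkpoint version mismatches, and
truncated checkpoints. Logged-and-continue: dropped expression rows with
missing values, duplicate pairs, unresolvable pair references, unparsable
SMILES, both-empty fingerprints (Tanimoto defined as 0), zero-variance tau
inputs. Checkpoints round-trip bit-exactly; loaders are deterministic; every
training and sampling routine is reproducible from its seed.

## Known limitations

Full-graph training only (no minibatching) — appropriate at these network
sizes, quadratic-memory dense path as cross-check only. No attention or
edge-weighted propagation (similarity scores are stored but not used in
message passing). Cold-start generalisation depends on how many same-module
entities remain after holdout and is intrinsically high-variance on small
networks. The pretrained drug-encoder path requires an external model; the
offline default is fingerprints.
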