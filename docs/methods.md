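# Methods

## Event derivation

Input is three deduplicated pairwise tables over string identifiers
(drug–target, drug–disease, target–disease) in two-column TSV. The entity
vocabulary is the union of observed identifiers per namespace, ordered
lexicographically; that order fixes every index, feature column and output
row, which is what makes runs bit-reproducible. For each drug–target pair
(X, Y) the treated-disease set is the intersection of X's diseases and Y's
diseases; pairs with an empty intersection are dropped. The intersection is
the only derivation rule consistent with reading the event as "X acting
through Y treats z": both the drug–disease and the target–disease evidence
must support each member of Z. Diseases that end up linked to no event are
kept as isolated nodes so the one-hot feature width z is stable across
splits.

Drug and target identities are stored as event *annotations*; only
event↔disease edges carry messages. All learnable structure lives on the
bipartite event–disease graph, which the decoder also scores, so adding
drug/target message-passing nodes would introduce parameters no output
consumes.

## Encoder

Two branches per layer, fused by gates and a residual:

* Projection. Per-type matrices map raw features to width d. Event raw
  features are the one-hot association row concatenated with a trainable
  free embedding (default width d); the free part lets two events with
  similar disease rows still differentiate. Both branches share the
  projection (separate per-branch projections would double parameters
  without changing expressiveness on this graph).
* Convolution branch. Up to k neighbors (default 10) are sampled uniformly
  without replacement per node per epoch; the node's state is aggregated
  with theirs (elementwise mean by default; sum is supported in the
  trainable path, max additionally in the per-node reference op), the
  concatenation [self ‖ aggregate] passes a fully connected layer and ReLU.
  Mean is the default because it is degree-robust.
* Attention branch. Full (unsampled) neighborhood; single-head additive
  attention with LeakyReLU slope 0.2 on the raw scores and a softmax per
  neighborhood. The central node's type selects the transform Wᵛ and score
  vector a, and both endpoints are transformed with that same Wᵛ. The
  attention-weighted neighbor sum is concatenated with the node state,
  rectified, and mapped back to width d by a learned linear map (the concat
  doubles the width; the residual sum needs d). Isolated nodes get a zero
  semantic part rather than an error inside the full forward pass.
* Gates and fusion. Each branch output x becomes x ⊙ σ(W_g x + b_g) (gates
  are per-branch, per-layer), and the layer returns
  gated-conv + gated-attention + input. Gating per branch uses each pictured
  component exactly once per layer and lets the model silence either branch
  per dimension.
* Dropout (inverted, rate 0.6 by default) is applied between layers, during
  training only. With dropout 0 and a fixed sampling seed the encoder is a
  pure function of (graph, features, parameters).

Activations: ReLU where the update formulas leave σ unnamed, LeakyReLU(0.2)
for attention scores (standard for that mechanism), sigmoid in the gate.

Default depth is L = 2. On the small synthetic benchmarks the 1-layer model
often trains fastest (it sees no between-layer dropout and has fewer
parameters); 2 layers remain the default as the configuration the ablation
surface is organized around.

## Decoder, loss, optimization

The default decoder aggregates the elementwise product of the event and
disease embeddings over the embedding dimension — a dot product — mapped to
a probability by a sigmoid. Ablation decoders: single-linear (one linear map
on the concatenated pair) and bilinear (uᵀBv). The loss is class-weighted
binary cross-entropy on logits in the overflow-free form
max(x,0) − x·y + log(1+e^−|x|) (exact to the naive form wherever that is
finite; no overflow for |x| up to 1e4). Optimizer: Adam with L2 weight decay
folded into the gradient. Defaults follow the tuned configuration: lr 1e-3,
batch 3840 (one full batch when a split is smaller, the usual case at desk
scale), embedding dim 64, dropout 0.6, weight decay 1e-5 (a conflicting
5e-5 reading exists; 1e-5 is the default and the knob is exposed), 200
epochs with the best-validation-AUC parameters returned — an unspecified
stopping rule handled conservatively.

Gradients come from `eventlink.autodiff`, a ~300-line reverse-mode engine on
float64 numpy arrays (no autodiff library is available in the target
environment). Every primitive and several layer-scale composites are checked
against central finite differences.

## Splits, negatives, leakage

Positive edges are permuted under the split seed and cut at ⌊0.6n⌋ and
⌊0.7n⌋ (train/validation/test 60/10/30, exact to ±1 edge). Negatives are
sampled uniformly without replacement from the enumerated non-edge
complement, 1:1 with positives per split by default, mutually disjoint
across splits, fixed at split time so validation/test metrics are stable
across epochs (per-epoch resampling of training negatives is available).
Message passing always uses training positives only; the adjacency actually
consumed is recorded on the returned model and history so tests can assert
no leakage.

One leak is inherited deliberately from the original design: the event
one-hot feature matrix is built from *all* event–disease associations,
including held-out ones, so node features partially encode the test labels.
This inflates absolute metrics on any benchmark. `features_from="train"`
rebuilds the one-hot rows from training edges only; the default keeps the
original behavior. The label-permutation control (below) shows the training
signal, not the feature leak alone, drives the reported AUC.

## Metrics

AUC is the Mann–Whitney statistic (ties count ½), AUPR the step-wise
average-precision rule; both delegate to scikit-learn and are cross-checked
in the tests against exhaustive pairwise concordance and hand-stepped
curves. Accuracy, precision, recall and F1 use the `probability ≥ 0.5` rule
(threshold exposed); zero-denominator cases return 0 rather than NaN so
ablation tables have no undefined cells. Curve exports use the standard
TPR = TP/(TP+FN) vs FPR = FP/(FP+TN) definitions (a transposed printing of
these two formulas exists upstream and is treated as a typo).

## Synthetic benchmark

The generator plants clusters: drugs, targets and diseases are assigned
uniformly to n_clusters groups; drug–target pairs form within a cluster with
p_dt = 0.3 (0.05·p_dt across — p_dt is not externally specified and was
fixed a priori to yield a few hundred events at the default scale);
drug–disease and target–disease associations are Bernoulli(p_within = 0.9)
within and Bernoulli(p_between = 0.02) across. Defaults (60 drugs, 40
targets, 120 diseases, 4 clusters) give ≈200 events and ≈5000 edges. What it
emulates: block-structured association tables whose derived events treat
cluster-coherent disease sets, so held-out links are predictable from
structure. What it does not emulate: real degree distributions (heavy
tails), identifier semantics, correlated noise, or database-scale sparsity —
a green signal-recovery test establishes that the pipeline learns planted
relational structure, not that it reproduces any real-data figure. On this
benchmark (dim 32, 200 epochs, 3 seeds) mean held-out AUC is ≈0.97;
permuting training labels drops it to ≈0.52, confirming the signal is
learned rather than leaked.

## Numerical and degenerate-input choices

* Softmax rows are stabilized by subtracting the (detached) row maximum;
  empty neighborhoods yield zero attention output instead of 0/0.
* Sigmoid and softplus use two-branch overflow-free forms.
* Ties in ranked predictions break by ascending disease index;
  identifier-order ties everywhere else break by index.
* Probability-at-threshold counts as positive (≥ rule).
* Empty input tables are legal (empty, not an error); malformed TSV lines
  raise with file and line number; an empty event set, empty training split,
  single-class AUC input and infeasible negative-sampling requests raise
  with specific messages.
* Seeds: every stochastic stage (generator, split, negatives, neighbor
  sampling, dropout, init, batch order) derives an independent stream from
  the run seed via `numpy` SeedSequence-style keys, so runs are
  bit-reproducible on one platform and no stage's draws shift another's.

## Known limitations

* Full-graph forward passes per epoch: fine at desk scale (hundreds of
  nodes), not built for database-scale graphs; minibatching re-encodes per
  batch.
* Single-head attention only; no edge features; no learning-rate schedules.
* The max aggregator is not differentiated in the trainable path (mean/sum
  are).
* Absolute metric levels on the default benchmark partially reflect the
  feature-construction leak described above; comparisons between variants
  share that leak and remain meaningful.
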