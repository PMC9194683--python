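# Methods

## Model

`metapathlink` predicts microbe–disease associations by embedding the
nodes of a tripartite heterogeneous network — microbes (m), drugs (c),
diseases (d) with undirected, unweighted m–d, m–c and d–c relations —
and scoring pairs by a sigmoid inner product. The architecture is a
metapath-aggregated graph neural network: per layer, metapath instances
are encoded by relational rotation, pooled per target node by multi-head
graph attention, and fused across metapaths by a semantic attention.

Assumptions worth stating explicitly:

* **Transduction.** All nodes are known at training time; only edges are
  held out. Validation and test positives are removed from the
  message-passing graph by default (`remove_heldout_edges`), so no test
  edge leaks into instance enumeration.
* **Homophily through intermediates.** The model's inductive bias is
  that microbes and diseases connected through shared intermediates
  (drugs, or other microbes/diseases) tend to associate. Networks whose
  association signal is not expressible through length-3 metapaths will
  not benefit from the architecture.
* **Binary, noise-free edges.** Edge weights, directions and evidence
  levels are out of scope.

### Relational rotation encoder

Each relation (m–c, m–d, d–c) owns a learnable phase vector
θ ∈ ℝ^{d/2}. A d-dimensional embedding is read as d/2 complex
coordinates (even columns real, odd imaginary); traversing an edge
multiplies the accumulator elementwise by e^{iθ} in the canonical
direction and by its conjugate e^{-iθ} in reverse, which is the natural
inverse of a rotation. Storing phases rather than free complex numbers
makes unit modulus structural instead of a constraint to penalise. The
encoder output for an n-node instance is the final accumulator divided
by n; for a single-node instance it reduces to the node vector itself,
and with all-identity rotations it reduces exactly to the arithmetic
mean of the node vectors (a property the tests exploit as an oracle).

A note on the accumulator normalisation: dividing the final accumulator
by the instance length is the convention adopted here; it keeps encoder
outputs on the scale of single-node embeddings regardless of metapath
length, and makes the identity-rotation case collapse to the mean
encoder used by the `avg` ablation.

### Attention stages and head dimensionality

Intra-metapath attention scores each instance by
LeakyReLU(δᵀ[h̃ᵢ ∥ h(M(i,j))]) (slope 0.01), normalises with a softmax
over the target's instances, and sums instance encodings; K heads with
independent δ are concatenated after an ELU. When several instances
connect the same (i, j) pair, each instance contributes its own
attention term — the normalisation runs over instances, not distinct
endpoints.

Each head aggregates at the full hidden width d, so the concatenated
output is K·d and the per-layer output map W_o ∈ ℝ^{d×Kd} projects back
to d. The alternative — splitting d across heads — forces d to be a
multiple of K, which the published defaults (d = 32, K = 6) do not
satisfy; full-width heads keep every configuration valid and make W_o
the single place where dimensionality is restored.

Inter-metapath attention is type-level by construction: a metapath's
summary is the mean over all nodes of its type of tanh(W·hᵢᴹ + b), so
the resulting weights β are shared by every node of that type. Per-node
semantic attention is a known alternative; the type-level form is
implemented as specified.

Nodes with zero instances of some metapath fall back to a
self-instance (the node alone), so every node receives an embedding and
attention softmaxes never see an empty set.

### Layers, initialisation, scoring, loss

Layer-0 embeddings are the rows of a learnable per-type projection
applied to one-hot inputs (equivalently: a free embedding table per
type). Drug-centred metapaths (c–m–c, c–d–c) are included so drug
embeddings are refreshed between layers; with L layers (default 2) the
last layer's drug parameters receive no gradient — final drug
embeddings are never scored — and the optimiser skips them. The
association score is sigmoid(h_mᵀh_d); the loss is binary cross-entropy,
−Σ_pos log C − Σ_neg log(1−C), with scores clamped to [1e−12, 1−1e−12]
before the logarithm.

## Training protocol

* Negative sampling: uniform over unobserved matrix cells, without
  replacement, 1:1 with positives, drawn once before splitting so
  validation/test negatives are fixed.
* Split: 8:1:1 train/validation/test, stratified by label.
* Optimiser: Adam (lr 0.005, weight decay 0.001 added to gradients) —
  conventional values for attention GNNs, exposed in config.
* Dropout 0.5 on layer inputs and attention coefficients, training mode
  only.
* Instance sampling: up to `neighbors` (150) instances per target node
  per metapath, resampled every epoch from the precomputed full
  enumeration (freeze with `resample_each_epoch: false`); evaluation
  always uses a fixed, seed-derived sample.
* Epochs: at most 100. Early stopping watches validation AUC with
  patience 10, but may only trigger after `min_epochs` (50). The reason
  for the floor is empirical and reproducible: optimisation is
  two-phase — a long plateau in which attention and embeddings align
  while the loss barely moves (often 20–40 epochs), then a loss
  collapse during which validation AUC climbs to its maximum. Stopping
  decisions taken inside the plateau are noise; with a shorter patience
  or no floor, runs reproducibly halted at around half their final
  validation AUC. The best-validation-AUC checkpoint is always restored
  regardless of when training stops.

All randomness (negatives, split, initialisation, per-epoch sampling,
dropout) derives from the single config seed; two runs with equal
config and seed produce identical histories.

### Ablation variants

* `nb` — instances encoded from target and endpoint only, rotated by
  the composed relation (the elementwise product of the traversed
  rotations); intermediate context is discarded.
* `sm` — the metapath catalogue is truncated to one metapath per type;
  every combination of singletons over the scored types (microbe,
  disease) is trained and the combination with the best validation AUC
  is reported. Auxiliary types keep their first metapath.
* `avg` — the rotation encoder is replaced by the coordinate-wise mean.

## Synthetic generator

`SyntheticSpec` plants `n_blocks` communities spanning all three node
types; each cross-type pair is linked independently with `p_in` inside
a block and `p_out` across. Defaults (n_m 150, n_c 40, n_d 60, 3
blocks, p_in 0.3, p_out 0.02, seed 1) give a microbe–disease density of
about 11% — far denser than real compilations (≈0.7%) but sized so that
a desk-scale network still contains thousands of metapath instances.
The generator reproduces the *mechanism* the model assumes (association
signal transitive through shared drug neighbourhoods); it does not
attempt the degree heterogeneity, ontology structure or annotation
biases of real databases, so test performance here demonstrates correct
mechanics, not clinical utility.

### The recovery ceiling

Within a block, edges are independent coin flips at `p_in`: conditioned
on block membership, a held-out positive cell and a never-linked cell
are statistically exchangeable, so no scorer can order them better than
chance. The Bayes-optimal score is therefore the block indicator. At the
default parameters, roughly 11% of held-out positives are cross-block
and 26% of the 1:1 uniformly sampled negatives are within-block, which
caps the expected held-out AUC of *any* method at about 0.81–0.82
(the block-indicator oracle, evaluated on the pipeline's own splits,
scores 0.813/0.819/0.845 for seeds 1/2/3). The trained full model
reaches a median test AUC of ≈0.82 on the same splits — i.e. it
saturates the generator's ceiling. Raising `p_in` toward 1 or shrinking
`p_out` raises the ceiling toward 1; the defaults deliberately keep a
noise floor so attention has something nontrivial to do.

## Numerical choices

* Float64 throughout; activation ELU (α=1) for aggregation and layer
  outputs, LeakyReLU slope 0.01 for attention scores — both
  configurable.
* Softmaxes (instance-level and semantic) subtract the detached
  per-group maximum before exponentiation; the shift cancels exactly in
  the gradient.
* Attention coefficient groups sum to 1 within 1e−6 (tested); scores at
  {0,1} are clamped by 1e−12 before logs and a warning is logged.
* Ties in candidate ranking break lexicographically by microbe id so
  exports are deterministic.
* Segment reductions run on sorted target groups via `reduceat`; the
  instance enumeration keeps rows grouped by target, and fallback
  self-instances are merged in sorted order.
* Gradients of every operation, and of the composed model, are verified
  against central finite differences in the test suite.

## Design choices on genuinely open points

* **Layer count** is not pinned by the published protocol; default 2
  (one layer cannot propagate drug-mediated evidence into both microbe
  and disease embeddings).
* **Attention-vector width 64** is applied to the semantic attention
  space (W, b, c); the intra-metapath vector δ is sized by the
  concatenation 2d it scores.
* **"Trained 100 times"** is read as 100 epochs, not 100 restarts.
* **Microbes without drug links** (real compilations contain many) are
  kept with empty drug neighbourhoods; their m–c–m aggregation falls
  back to self-instances.
* **Loss sign**: the negative-sample term is log(1−C), the standard
  cross-entropy complement.

## Limitations

* Full-batch training on a single graph; no minibatching, no GPU path.
  Practical up to a few thousand nodes and ~10⁵ metapath instances.
* Metapaths are capped at length 5 and must start and end at the
  embedded type; relations are unweighted and undirected.
* The synthetic fixture validates mechanics, not real-data performance;
  results on curated databases depend on identifier unification and
  curation quality, which the package deliberately does not address
  (ids are opaque strings; only case/whitespace near-collisions are
  warned about).
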