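# Methods

## Problem and model

Given miRNA functional similarity `SM` (m×m), disease semantic similarity
`SD` (n×n) and a binary association matrix `A` (m×n), the task is to score
every unverified miRNA–disease pair. Both similarity matrices are assumed
symmetric, valued in [0, 1] with unit diagonal; computing them from raw
biological data (miRNA target profiles, MeSH ontology) is out of scope —
they are inputs.

The heterogeneous adjacency is the block matrix `A_H = [[SM, A], [Aᵀ, SD]]`
with miRNAs on indices `0..m−1` and diseases on `m..m+n−1`; this node order
is fixed everywhere. The propagation operator of the GCN is
`Â_H = D^{−1/2} A_H D^{−1/2}` with `D` the diagonal row-sum (degree)
matrix. No extra self-loop term is added: the unit similarity diagonals
already act as self-connections. An isolated node (zero degree) gets a zero
row/column in `Â_H` rather than a division by zero — propagation from and
to it is null. The symmetric normalized Laplacian
(`1` on the diagonal of supported nodes, `−A_ij/√(d_i d_j)` off it) is
provided for spectral analysis; the model itself consumes `Â_H`.

## Restart-walk features

Similarity estimates are noisy; using raw similarity rows as node features
propagates that noise. Instead each node's feature vector is the
stationary distribution of a random walk with restart on its own
similarity network: `r^{k+1} = c W r^k + (1−c) e_i`, where `W` is the
column-normalized similarity (interpreting `W[i, j]` as flow from `j` into
`i`) and `c ∈ (0, 1)` the probability of continuing the walk. The fixed
point `(1−c)(I−cW)^{−1} e_i` exists because `c < 1`; the iterative solver
stops when the L1 change drops below `tol`. Columns of an all-zero
similarity fall back to the uniform distribution so `W` stays stochastic.

Defaults: `c = 0.5` (balanced between locality and global structure),
`tol = 1e−8`, `max_iter = 1000`. Rows are L1-normalized into `RM` and
`RD`, and stacked into the combined feature matrix `A_F`. The block
placement is **diagonal** (`[[RM, 0], [0, RD]]`) so each node's feature row
is its propagation profile over its own node type; a zero-padded
off-diagonal placement is available behind `feature_placement` for
comparison, because the cross-type layout cannot hold the square blocks
without padding (they are m×m and n×n while the cross blocks are m×n and
n×m).

## Network and training

* GCN layer: `F = ReLU(Â_H A_F W⁰)`, `W⁰ ∈ R^{(m+n)×h}`, Xavier-uniform
  initialized. Exactly one convolution layer is used; the reinforcement
  layer is the second (and last) hidden transformation.
* Attention reinforcement: neighborhoods `N_i` are the nonzero
  off-diagonal entries of `A_H` (similarity plus association edges; a
  `top_k` rule is available). The default score is the transformed dot
  product `e_ij = ReLU((W h_i)ᵀ(W h_j))` with a separate trainable
  `W ∈ R^{h×h}`; a concatenation variant
  `e_ij = ReLU(aᵀ[W h_i ‖ W h_j])` sits behind `attention_score="concat"`.
  Coefficients are the row softmax of `e` over `N_i`; a node with an empty
  neighborhood keeps its own embedding (pass-through) and contributes
  nothing to the penalty. The aggregation uses the *neighbor* vectors,
  `H_i = Σ_{j∈N_i} a_ij h_j` — aggregating the node's own vector would
  make the attention weights vacuous since they sum to one.
* Reinforcement penalty: `L_H = Σ_i Σ_{j∈N_i} a_ij ‖H_i − H_j‖²`,
  evaluated on the reinforced embeddings. It is nonnegative, zero iff
  attended neighbors coincide, and scales quadratically with the embedding
  scale.
* Decoder: `Y = sigmoid(H_r W′ H_dᵀ)` with `W′ ∈ R^{h×h}` (the decoder
  width equals the embedding width `h`).
* Loss: `L = L_cross + λ L_H`, where `L_cross` is the *summed* binary
  cross-entropy over the verified positives `y` and the unknown pairs
  `y⁻` (all of them by default; a seeded `r`-negatives-per-positive
  sampler exists for large instances). Scores are clipped to
  `[1e−12, 1−1e−12]` before the logs. How the two losses combine is a
  design choice of this package; `λ = 0.1` by default and `λ = 0` recovers
  pure cross-entropy training.
* Optimization: plain full-batch gradient descent, fixed learning rate
  0.01, 500 epochs by default. Gradients are derived analytically
  (including the paths through the attention softmax and the penalty's
  dependence on both the coefficients and the aggregated embeddings) and
  are validated against central finite differences to 1e−4 relative error
  in the test suite. All randomness (initialization, negative sampling,
  fold partitions) derives from named sub-streams of one seed, so runs are
  bit-reproducible.

ReLU and the attention score are non-smooth at 0; the implementation uses
the standard subgradient (0 at the kink), and gradient checks probe random
parameter entries where the loss is differentiable with probability one.

## Evaluation protocols

Every verified association is a test sample in turn. *Global* LOOCV ranks
its score against all unverified pairs pooled over every disease; *local*
LOOCV only against the unverified miRNAs of its own disease; k-fold CV
(default k = 5) partitions the positives into near-equal random folds per
repeat, masks each fold, retrains, and ranks the fold's positives against
the unverified pairs. AUC is the mean Mann–Whitney contribution of the
test samples (ties count one half), which equals the trapezoidal ROC area;
AUPR is average precision; ACC thresholds at 0.5 against an equal-size
seeded sample of candidate scores (the choice of negative set for ACC is a
package decision and configurable). LOOCV offers both a faithful
retrain-per-held-out-pair mode and a cheap frozen-scorer mode
(`retrain=False`), because full retraining is O(#positives) trainings;
both are exposed and the mode is always explicit in the protocol object.

## Synthetic benchmark

The generator emulates the structure the model exploits: `g_m` miRNA
groups and `g_d` disease groups with constant within/between similarity
(0.9 / 0.05 by default) plus clipped symmetric Gaussian noise
(sd 0.05), unit diagonals, and associations drawn Bernoulli per
(miRNA group × disease group) block — by default one dense block at 0.6
against a 0.02 background, 60 miRNAs × 40 diseases. Group sizes are
near-equal contiguous ranges (remainder to the first groups) for
determinism.

What it does *not* emulate: the heavy-tailed degree distribution of real
association databases, correlations between similarity and degree, and the
ontology-induced geometry of real semantic similarities. Passing the
recovery tests therefore shows the pipeline can exploit block-structured
signal end to end, not that it attains any particular accuracy on real
HMDD-scale data.

## Ablations

Replacing the reinforcement layer with a plain hidden GCN layer
(`reinforce_mode="gcn"`), or the RWR features with raw similarity rows
(`use_rwr=False`), lowers mean fivefold AUC on the benchmark. Two caveats
are worth stating honestly. First, the raw-feature baseline feeds rows
whose sums are ≈ degree (tens) rather than 1; at the shared learning rate
this collapses the ReLU layer (all-tied scores, AUC 0.5), so part of what
the restart-walk extraction provides here is simply bounded, normalized
features. Second, if the raw rows are L1-normalized instead, they act as a
one-step walk and perform indistinguishably from the RWR features on this
low-noise benchmark — the advantage of the full walk is expected to grow
with similarity noise, which is exactly its motivation.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at
60×40 nodes, h = 32, 200 epochs, fivefold CV over 5 seeds (recovery) and
10 seeds (ablations); these sizes keep the planted signal realistic while
the dense linear algebra stays small. Embedding dimension default is
h = 32 at benchmark scale — accuracy rises with h on larger data, and the
config exposes the sweep ([32, 64, 128, 256, 512]). Degenerate inputs are
defined, not special-cased: empty neighborhoods pass through, zero-degree
nodes propagate nothing, zero similarity columns teleport uniformly, and a
non-finite training loss raises with the offending epoch.

## Known limitations

* Full-batch dense training: memory and time are O((m+n)²); the package
  targets networks of up to a few thousand nodes, not genome-scale graphs.
* Plain gradient descent with a fixed rate — no momentum, no scheduler;
  very large feature scales can kill the ReLU layer (see the ablation
  caveat).
* The decoder scores depend on the sign structure of `W′`; scores are
  calibrated only up to the training prevalence, so thresholded accuracy
  is less informative than the ranking metrics.
* Single attention head and a single GCN layer by design; deeper stacks
  are out of scope.
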