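# Methods

## Model

`hetlink` treats protein–lncRNA interaction prediction as supervised
link prediction on a two-type heterogeneous network. The premise is that
interaction signal is carried by network proximity: interacting pairs
tend to be close in the merged PP/LL/PL graph, both in the diffusion
sense (random walks started at one endpoint visit the other's
neighborhood) and in the metapath sense (many short typed paths connect
them). Two feature families capture these two notions and a
gradient-boosted tree ensemble combines them.

### Network construction

Edges carry similarity weights in [0, 1]. Co-expression evidence from
multiple datasets is integrated per pair as `C = 1 − Π (1 − C_d)` over
the datasets with positive Pearson correlation; pairs whose correlations
are all non-positive are discarded, on the reasoning that mutual
exclusion argues against interaction. Note the integration is taken at
face value when some `C_d = 1` exactly: the integrated value is then 1
regardless of the other datasets. Edges with weight < 0.5 are removed
(the cutoff is configurable per edge class; weights on other scales,
e.g. 0–1000 confidence scores, must be rescaled before input). The
surviving edges form a binary symmetric adjacency `G` with zero
diagonal; a weighted mode is available but binary is the default, and
known experimental PL interactions enter at weight 1.0 so they always
survive the cutoff. Nodes that lose all edges stay in the registry (so
indexing is stable) and appear as isolated rows.

### Diffusion embedding

The transition matrix is the row normalization of `G`; isolated nodes
get a self-loop `T_ii = 1`, which keeps `T` stochastic and makes their
diffusion state the trivial point mass. The restart walk
`p_{t+1} = (1−α) T′ p_t + α p_0` is applied to column vectors with the
transposed matrix so that probability flows from node *i* to node *j*
with probability `T_ij` and every iterate remains a distribution. The
restart probability defaults to α = 0.5 and is exposed as a parameter;
the method is not sensitive to it in the benchmark regime but no single
canonical value exists. Iteration stops when the L1 change drops below
`tol` (default 1e-6, max 1000 iterations; non-convergence raises with
the residual). A direct sparse linear solve of
`S = α (I − (1−α)T)^{-1}` is available as an exact mode and is the
preferred solver up to a few thousand nodes.

The diffusion-state matrix is reduced by SVD. Writing `S = U Σ Vᵗ`, each
node is embedded as a row of `X = V_n Σ_n^{1/2}`; the singular values of
`X` are therefore the square roots of the top-n singular values of `S`
(this is asserted in the test suite). Right-singular-vector signs are
fixed so the largest-magnitude entry is positive, making the embedding
deterministic across runs and platforms. The default output dimension is
n = 500; when the network has fewer than n singular directions the
embedding is padded with zero columns (with a warning) rather than
truncated, so the downstream feature length is stable — a requirement
for serialized models to be portable across networks of different sizes.

### HeteSim scores

The metapath catalogue is every type string from protein to lncRNA with
3–5 node symbols: 2 + 4 + 8 = 14 paths, in a frozen order (PLL, PPL,
PPLL, PLPL, PLLL, PPPL, PPPPL, PLPPL, PPLPL, PLLPL, PPPLL, PLPLL, PPLLL,
PLLLL). The direct 2-node path PL is excluded from features — it is the
label. The score of a pair along a path is the standard HeteSim
relevance: split the path at its midpoint, propagate a walker from the
protein along row-normalized typed adjacencies of the left half and a
walker from the lncRNA along the reversed right half, and take the
cosine of the two arrival distributions (0 if either walker reaches
nothing). Paths with an odd edge count are split by middle-edge
decomposition: each directed instance of the central relation becomes a
virtual midpoint, with each endpoint distributing its mass uniformly
over its incident central edges. All-zero rows stay zero under
normalization (a node with no out-edges of a relation reaches nothing
via it), and the matrix-product semantics count walks, not simple paths
— revisiting nodes is allowed. Typed adjacencies are binary by default,
matching the binary global adjacency.

During training the pair's own direct PL edge (when present) is removed
before its scores are computed (`mask_query_edge`), so a supervised pair
cannot read its label off the network; for novel-pair prediction the
flag is off, as no direct edge exists. Scores are pairwise quantities;
the feature vector is per (protein, lncRNA) pair, 14 entries in
catalogue order.

### Classifier

The combined vector `[embedding(p) | embedding(l) | HeteSim]` has
2n + 14 entries (1,014 at n = 500); the length is checked at both train
and predict time, and models persist their feature schema so a mismatch
hard-fails instead of silently drifting. The classifier is scikit-learn's
`GradientBoostingClassifier` — a stagewise additive expansion
`Θ_m = Θ_{m−1} + β_m h(χ; α_m)` fit to the logistic loss
`log(1 + exp(−yΘ))` with y ∈ {+1, −1} internally ({1, 0} in files).
Defaults follow the full-scale setting: 600 trees of depth 13 with
learning rate 0.1 and no subsampling (both exposed; the learning rate
and subsample fraction have no canonical published value). Grid search
over (trees, depth) with stratified 10-fold CV picks parameters by mean
AUC, breaking ties toward the smaller model.

## Synthetic benchmark

The generator is a planted-partition model: proteins and lncRNAs are
assigned uniformly to `n_modules` modules; PP and LL edges are Bernoulli
with rate `p_within` inside a module and `p_between` across; true PL
interactions occur only within modules at rate `pl_within`; a
`noise_rate` fraction of true interactions is hidden from the network
and becomes the positives to recover. Defaults: 200 proteins, 200
lncRNAs, 5 modules, p_within = 0.3, p_between = 0.02, pl_within = 0.3,
noise_rate = 0.3. LL weights are drawn from Beta(5, 2) — mostly above
0.5, so the edge-weight threshold removes a realistic minority (~11 %)
of co-expression edges; PP and observed PL edges carry weight 1.0.
Benchmarks split the hidden positives into disjoint train/test halves
and sample negatives uniformly from the non-interacting pairs at ratios
1:1 through 1:10.

What the generator does *not* emulate: scale-free degree distributions,
correlated noise between the PP and LL layers, expression-level
measurement error (weights are drawn directly, not computed from
simulated profiles), and the extreme class imbalance of a real
genome-wide candidate space. Passing the benchmark therefore shows the
pipeline recovers proximity-encoded interactions under clean modular
structure; it does not certify performance on real corpora, where hubs,
annotation bias and contaminated negatives all matter.

### Benchmark problem sizes

End-to-end checks run at desk scale: the generator defaults above
(400 nodes), embedding dimension 32, and a 100-tree / depth-5 boosting
model, cross-validated 10-fold over three generator seeds. The embedding
and ensemble are deliberately smaller than the full-scale defaults
(500 / 600 / 13): a 400-node network has at most 400 informative
singular directions, and tree depth beyond ~5 adds nothing at a few
hundred training pairs. The full-scale defaults remain the library
defaults for real-size networks. On this benchmark the combined features
reach mean CV AUC ≈ 0.92–0.93, with the HeteSim group alone comparable
and the diffusion group alone weaker (≈ 0.8) — expected, since module
membership (what the embedding encodes) upper-bounds how well
within-module non-interactions can be separated, whereas HeteSim sees
pair-specific path structure. Permuting labels collapses CV AUC to 0.5,
confirming the signal is real and not a leak.

## Numerical choices

- RWR convergence is measured in L1; tolerance 1e-6 by default, 1e-13 in
  oracle-agreement tests (the fixed-point error is bounded by
  `tol·(1−α)/α`).
- SVD uses LAPACK full SVD (networks at desk scale are small); sign
  convention as above; zero-padding beyond rank.
- HeteSim cosine is clipped to [0, 1] to absorb rounding at the 1e-16
  level; exact zeros are produced when either half-walk dies.
- AUC uses midrank tie handling; confusion-matrix metrics define 0/0 as
  0 with a warning; folds are stratified by label (configurable off).
- All randomness (generator, negative sampling, fold shuffling, boosting
  subsampling) flows through explicit integer seeds.

## Known limitations

- Diffusion states are computed densely (one restart per node); beyond a
  few thousand nodes the direct solver and a truncated SVD would be the
  right tools, and the current implementation does not provide them.
- HeteSim masking recomputes a pair's scores on a modified network one
  pair at a time; for training sets dominated by observed direct edges
  this is the slow path.
- Negative sampling excludes only *known* positives, so sampled
  negatives can contain undiscovered true interactions; this mirrors the
  standard evaluation protocol and slightly deflates measured precision.
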