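# Methods

## Preprocessing

Cells are filtered on three QC criteria: mitochondrial count fraction
(default ≤ 5%, genes matched by the `MT-` identifier prefix), number of
expressed genes (default 100–10,000), and an optional barcode exclusion
list (e.g. doublets called by an external tool). Genes may be filtered by a
minimal-expression rule (expressed in ≥ 3 cells by default); the thresholds
are deliberately conventional and fully configurable.

Normalization is total-count scaling: every cell is scaled so its total
equals L, the median raw per-cell depth (size factor = cell total / L),
followed by log1p. The natural log is used throughout.

Highly variable genes are chosen against a parametric mean-variance trend.
Per-gene mean μ and variance σ² of the log-normalized matrix are fitted
with

    σ² = a·μ / (μ^p + b),

by bounded nonlinear least squares (a, b ≥ 1e-8; exponent p ∈ (0, 10],
initialized at 1 and fitted rather than pinned — the family subsumes the
common p = 1 saturation curve while letting the data choose the decay).
Genes with zero variance are excluded from the fit but still receive a
deviation (0 − expected). The selection keeps the `n_hvg` genes (default
5000) with the largest observed-minus-expected variance, ties broken by
gene index for determinism.

For the neural network the log-normalized matrix is additionally
standardized **per cell** to mean 0, population sd 1. Per-cell scaling (as
opposed to the per-gene scaling some upstream tools use) is the package's
default because the encoder consumes cells as samples; a per-gene switch
(`axis='genes'`) is provided.

## k-MST + Louvain

Cell-cell similarity is the Pearson correlation of the (log-normalized,
HVG-restricted) expression vectors; zero-variance cells are a hard error
because their correlation is undefined. The MST cost is d = 1 − c ∈ [0, 2].

The graph is built by k iterations of Kruskal's algorithm, k = max(1,
⌈ln n⌉) by default: each iteration computes the minimum spanning tree (or
forest, if removing earlier trees disconnected the residual graph) over the
edges not yet selected and removes it. Edges are sorted by (weight, i, j)
so ties resolve identically across runs. Later trees draw from a depleted
edge set, so per-tree total weights are non-decreasing; while residual
graphs stay connected every node ends with degree ≥ k.

Louvain runs on the union graph with each edge carrying its similarity
value; edges with non-positive similarity are dropped, since modularity
with negative weights is ill-defined. Modularity is evaluated in the
directed form (both ordered directions materialized, T = sum over ordered
pairs), which for an undirected graph equals the standard Newman
modularity with w_out = w_in = weighted degree. The optimizer is the
classical two-phase scheme — greedy local moves in seed-shuffled node
order, then community aggregation — iterated until modularity stops
improving. Fixed seed ⇒ bit-identical partitions.

Degenerate guard: if every off-diagonal correlation is 1 (all cells
duplicates), the pipeline short-circuits to a single community instead of
building a zero-distance graph.

## ZINB autoencoder

Counts are modeled per entry as zero-inflated negative binomial:

    NB(k | μ, θ) = Γ(k+θ)/(Γ(θ) k!) · (θ/(θ+μ))^θ · (μ/(θ+μ))^k
    ZINB(k) = π + (1−π)·NB(0)   if k = 0;   (1−π)·NB(k)  if k > 0

The encoder is a dense stack (default sizes [64, 32] → latent 32, rectifier
activations, linear latent layer); the decoder mirrors it and ends in three
heads: π via logistic, μ = size_factor · exp(·) with the pre-activation
clamped to ±15, θ via softplus clamped to [1e-4, 1e4]. Routing the library
size through the μ head keeps depth out of the latent space. The loss is
the mean −log ZINB over entries; gradients with respect to the three head
pre-activations are derived analytically (the k = 0 mixture term couples
all three parameters through A = π + (1−π)·NB(0)) and verified against
finite differences in the test suite. Optimization is Adam (lr 1e-3, batch
256); defaults are 300 pretraining epochs, scaled down to 30 in tests and
the acceptance run, which suffices for the loss to fall and the latent
space to organize at the fixture's problem size (500 × 300).

Everything is numpy: a fixed seed fixes initialization and batch order, so
training is bit-reproducible on CPU.

## Cluster-count estimation and GMM fine-tuning

After pretraining, the k-MST + Louvain procedure runs on the latent
vectors (Pearson correlation between latent codes — the same machinery as
the main algorithm); the number of communities K becomes the mixture size.
A Gaussian mixture is moment-matched to the communities: means =
centroids, covariances = diagonal sample covariances floored at 1e-4
(singleton clusters get floor·I), weights = frequencies.

Fine-tuning minimizes the mixture NLL jointly over encoder weights and
mixture parameters by Adam (default 100 epochs; 20 in tests/acceptance).
Mixture weights are parameterized through a softmax and variances as
floor + exp(v), so the probability simplex and the positive-definiteness
floor hold by construction at every step. The decoder is frozen in stage
two (the reconstruction task has done its job shaping the latent space; an
optional λ·ZINB regularizer, default λ = 0, re-enables gradient flow
through the frozen decoder into the encoder). Covariances are diagonal:
axis-aligned ellipsoids keep the flexible cluster shapes of a full GMM
without the singularity risk of full covariances in 32 dimensions.

Soft assignments are the responsibilities r_ic = π_c N(z_i; μ_c, Σ_c) /
Σ_c' π_c' N(z_i; μ_c', Σ_c'), computed in log space (log-sum-exp), so
far-away points never produce NaN rows; hard labels are the row argmax
with ties to the lowest index.

## Evaluation metrics

Accuracy is the optimal-assignment matching fraction: maximum number of
agreeing cells over injective maps between predicted and true labels,
solved by the Hungarian algorithm on the contingency table and divided by
n. NMI uses the arithmetic-mean normalization of the two entropies; ARI is
the chance-corrected pair-counting index. NMI and ARI are delegated to
scikit-learn; all three are checked against exhaustive brute-force oracles
on every partition pair of small sets in the test suite.

Reference annotation averages a reference expression table per cell type,
computes each query cell's Pearson correlation against each type on the
shared gene set, and assigns the argmax (ties → first type in reference
order; constant profiles are skipped with a warning).

## Synthetic data

The generator draws per-gene base means log-normally (median 0.08, log-sd
1), plants cluster structure by shifting a random 30% of genes per cluster
by ±2.5 natural-log units, multiplies in a log-normal per-cell library
factor (sd 0.25), samples counts by gamma-Poisson composition (NB with
dispersion 2), and finally zeroes entries independently with probability
0.45. The default preset (500 cells × 300 genes, 4 equal clusters) lands
at 90–92% zeros — the sparsity regime of real droplet experiments — while
remaining recoverable (planted-label ARI ≥ 0.9 for k-MST across seeds).

What the generator does *not* emulate: gene-gene correlation beyond
cluster membership, batch effects, trajectories/continuous states, and
cell-type-specific dropout. Passing the recovery tests therefore shows the
algorithms work under well-separated mixture conditions at moderate n, not
that they match any particular accuracy on real tissue data.

Latent-space fixtures come from `simulate_blobs` (isotropic Gaussians at
mutually distant centers).

## Numerical choices and edge cases

- All likelihoods evaluated in log space; ZINB zero-branch via
  logaddexp, GMM via log-sum-exp.
- Kruskal ties: lexicographic (weight, i, j). Louvain: equal-gain moves
  resolve to the first candidate in sorted community order.
- Zero-total cells, constant cells/genes, empty filter results, missing
  sidecar files and non-integer counts each raise a distinct named error.
- Problem sizes in tests and the acceptance script (500 × 300, 30/20
  epochs) were chosen as the smallest sizes at which the statistical
  properties of interest are stable across seeds.

## Known limitations

- The n × n correlation matrix and k Kruskal passes make k-MST O(n²g +
  n² log n); tens of thousands of cells are feasible, but slower than
  approximate-neighbor graph methods.
- The numpy network is CPU-only and unbatched in the feature dimension;
  very wide matrices (tens of thousands of genes) should be HVG-filtered
  before `AEGMMCluster`.
- Cluster-count estimation inherits Louvain's resolution behavior: strong
  substructure within a true cluster may split it (the worked example's 5
  communities on 4 planted clusters is exactly this).
- The generator's dropout is independent of expression level; real dropout
  is mean-dependent.
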