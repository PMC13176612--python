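# sccluster

Unsupervised cell clustering for single-cell RNA-seq count matrices.

Identifying cell types is the first analysis step after quantifying gene
expression per cell, and it is hard for three reasons: the data are
high-dimensional (thousands of genes), extremely sparse (often more than 90%
zeros), and contaminated by *dropouts* — technical zeros where a transcript
was present but not captured. `sccluster` implements two complementary
algorithms for this problem, for bioinformaticians who want cluster labels
(and a cluster-count estimate) straight from a raw count matrix:

**k-MST + Louvain.** From the log-normalized matrix restricted to the genes
with the highest upward deviation from a fitted mean-variance trend, the
pairwise Pearson correlation

&nbsp;&nbsp;&nbsp;&nbsp;c<sub>ij</sub> = cov(x<sub>i</sub>, x<sub>j</sub>) / (σ<sub>x<sub>i</sub></sub> σ<sub>x<sub>j</sub></sub>)

defines a cell–cell similarity. The graph is the union of k = ⌈ln n⌉
edge-disjoint minimum spanning trees, built iteratively: each round runs
Kruskal's algorithm on the distance d<sub>ij</sub> = 1 − c<sub>ij</sub> over
the edges not selected in earlier rounds. Unlike a k-NN graph every node
still has degree ≥ k, but well-connected cells keep more edges. Communities
come from Louvain modularity optimization,

&nbsp;&nbsp;&nbsp;&nbsp;M(G, C) = Σ<sub>i,j : C(i)=C(j)</sub> [ e<sub>ij</sub>/T − w<sub>out</sub>(i) w<sub>in</sub>(j)/T² ],

and the number of communities is the cluster-count estimate.

**AE-GMM.** A small autoencoder is pretrained on the raw counts with a
zero-inflated negative binomial (ZINB) reconstruction loss — dropout
probability π<sub>ij</sub>, NB mean μ<sub>ij</sub> and dispersion
θ<sub>ij</sub> per matrix entry — so the latent space reflects count noise
rather than Euclidean error. The k-MST procedure on the latent space fixes
the number of clusters; a Gaussian mixture (π<sub>c</sub>, μ<sub>c</sub>,
Σ<sub>c</sub>) is moment-matched to those communities and then encoder and
mixture are fine-tuned jointly on the mixture negative log-likelihood
L<sub>GMM</sub> = Σ<sub>i</sub> −ln Σ<sub>c</sub> π<sub>c</sub>
N(z<sub>i</sub>; μ<sub>c</sub>, Σ<sub>c</sub>), yielding soft (per-cell
probabilistic) assignments. The network is plain numpy with hand-derived
gradients, so CPU runs are fully deterministic per seed.

Both pipelines are exposed as scikit-learn style estimators
(`KMSTCluster`, `AEGMMCluster`) and as a CLI with `simulate`, `kmst`,
`aegmm`, `evaluate` and `annotate` subcommands.

## Worked example

```python
from sccluster import (AEGMMCluster, KMSTCluster, KMSTConfig, SimConfig,
                       ari, nmi, simulate_zinb_mixture)

sim = simulate_zinb_mixture(SimConfig(seed=1))   # 500 cells x 300 genes, 4 clusters
print(f"zeros: {sim.counts.zero_fraction():.2%}")

km = KMSTCluster(seed=1).fit(sim.counts)
print(f"k-MST: {km.n_clusters_} clusters, modularity {km.modularity_:.4f}, "
      f"ARI {ari(sim.labels, km.labels_):.4f}")

ae = AEGMMCluster(pretrain_epochs=30, finetune_epochs=20, seed=1).fit(sim.counts)
print(f"AE-GMM: {ae.n_clusters_} clusters, "
      f"NMI {nmi(sim.labels, ae.labels_):.4f} "
      f"(init {nmi(sim.labels, ae.init_labels_):.4f})")
```

prints

```
zeros: 91.57%
k-MST: 5 clusters, modularity 0.7162, ARI 0.9058
AE-GMM: 5 clusters, NMI 0.8923 (init 0.8600)
```

The simulated matrix sits in the ≥ 90%-zeros regime typical of droplet
data. k-MST recovers the planted 4-cluster structure almost perfectly
(ARI 0.91; it splits one cluster, hence 5 communities). For AE-GMM, the
fine-tuning stage lifts agreement with the planted labels from NMI 0.860
(the latent-space k-MST initialization) to 0.892 — the GMM stage refines,
rather than degrades, the initial partition.

The same flow from a shell:

```bash
sccluster simulate --n-cells 500 --n-genes 300 --seed 1 --out-prefix sim
sccluster kmst --input sim.mtx --seed 1 --out pred.tsv
sccluster evaluate --truth sim_labels.tsv --pred pred.tsv --out metrics.json
```

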