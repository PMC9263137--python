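# kcselect

Unsupervised feature selection for clustering high-dimensional expression
data, built around the **Kriging-Correlation (KC) score**: the correlation
between a feature and its reconstruction from a learned low-dimensional
embedding of the cells.

## Who this is for

Analysts clustering cells × genes matrices (typically scRNA-seq, where
*n* ≪ *p*) who want to know *which genes drive the cluster structure* and
to cluster on a compact gene subset instead of the full matrix.  Zeros
from dropout are taken as-is — dropout *patterns* are themselves an
informative signal this method exploits.

## The method

**KC score.**  Cells are embedded to `Z ∈ R^{n×d}` (default d = 2) by
t-SNE driven by a learned cell-cell similarity.  A multi-resolution
thin-plate spline basis `G` (constant + linear terms + eigenvectors of the
projected thin-plate kernel `QΦQ`) is evaluated at the latent locations,
and each gene is fit with the spatial random-effect model

    x = G w + η,   w ~ N(0, M),   η ~ N(0, σ² I),

by fixed-rank-kriging maximum likelihood with AIC rank selection.  The
score is `KC_k = Cor(x_k, x̂_k)` with `x̂` the posterior-mean fit; genes
that vary smoothly over the embedding (i.e. track cluster structure)
score near 1.

**Similarity.**  Either a single locally-scaled Gaussian kernel (mode G),
or a 55-kernel bank (k ∈ {10,12,…,30} × σ ∈ {1.0,1.25,…,2.0}) mixed by
learned weights through the multi-kernel objective

    min_{S,L,w}  Σ_ij D(x_i,x_j) S_ij + β‖S‖_F² + γ tr(Lᵀ(I−S)L) + ρ Σ_l w_l log w_l

with S row-stochastic, w on the simplex, LᵀL = I_C (mode M), solved by
exact block alternating minimization.

**Selection pipeline.**  Score and order genes; for subset sizes k on a
grid, embed the top-k genes and cluster by k-means; pick
`k1 = argmax_k 𝓕(V_k)` where 𝓕 is MANOVA's Pillai trace
`tr(B(B+W)⁻¹)`; prune to
`k2 = 1 + max{k < k1 : NMI(ŷ(V_k), ŷ(V_k1)) < 0.95}`; accept the
single-kernel result if its NMI against the all-features multi-kernel
clustering exceeds 0.7, otherwise rerun with the multi-kernel similarity.
A Laplacian-score baseline (`L_k = x̃ᵀ(D−S)x̃ / x̃ᵀDx̃`, smaller = more
important) is included, as are the evaluation metrics NMI, Pillai's
trace, NNA (5-fold 1-NN accuracy) and RFA (5-fold random-forest
accuracy).

## Worked example

Three cell classes distinguishable *only* by the dropout patterns of two
genes, hidden among 500 noise genes:

```python
from kcselect import RunConfig, nmi, simulate_dropout_pattern, strategy_a

X, y = simulate_dropout_pattern(n=90, p_noise=500, seed=0)
result = strategy_a(X, C=3, score_method="kc",
                    config=RunConfig(n_clusters=3, seed=1))
```

Output (`examples/select_dropout_genes.py`):

```
k1 (Pillai-trace argmax) : 51
k2 (after NMI pruning)   : 2
selected genes           : ['geneA', 'geneB']
kernel mode used         : G
adequacy NMI             : 1.000
NMI vs true classes      : 1.000
```

The pipeline prunes from 502 genes down to exactly the two diagnostic
genes (`k2 = 2`) and clusters the 90 cells perfectly (NMI = 1): the
(zero, zero) / (zero, expressed) / (expressed, expressed) patterns of the
two genes are the three classes.  The other scripts in `examples/` show
gene scoring, the Laplacian baseline, and metric evaluation, each a few
seconds to run.

A thin CLI wraps the same calls:

```sh
kcselect simulate --preset dropout --n 90 --p-noise 500 --out-prefix demo
kcselect select --input demo.csv --clusters 3 --score kc --seed 1 --out report.json
```

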