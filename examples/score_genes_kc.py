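"""Score genes by the Kriging-Correlation (KC) score on planted-cluster data.

Simulates 200 cells × 300 genes with 15 marker genes, learns a multi-kernel
similarity, embeds by t-SNE, and correlates each gene with its fixed-rank
kriging reconstruction from the embedding.  Marker genes should dominate
the top of the ranking.
"""

import numpy as np

from kcselect import (
    SimulationSpec,
    kc_score,
    rank_features,
    similarity_to_affinities,
    simlr_similarity,
    simulate_classes,
    tsne_embed,
)

X, y = simulate_classes(
    SimulationSpec(n=200, p=300, n_informative=15, effect_size=3.0, seed=0)
)
state = simlr_similarity(X, C=3)
Z = tsne_embed(similarity_to_affinities(state.S), seed=0)
scores = kc_score(Z, X)
top = rank_features(scores, 15)

print("top 15 genes by KC score:")
for i in top.indices:
    print(f"  {X.gene_ids[i]:<12} KC = {scores.scores[i]:.3f}")
markers = sum(X.gene_ids[i].startswith("marker") for i in top.indices)
print(f"\n{markers}/15 of the top genes are planted markers.")
print("KC near 1 means the gene varies smoothly over the latent space, i.e.")
print("it tracks the cluster structure; noise genes score near 0.")
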