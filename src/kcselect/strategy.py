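"""The four-step feature-selection pipeline.

Given a cells × genes matrix X and a cluster count C:

0. learn the multi-kernel similarity S^M(X), embed to Z^M(X), cluster to
   y^M(X); score every gene (KC score from Z^M(X), or Laplacian score from
   S^M(X)) and order genes by importance;
1. for each subset size k on a grid, embed the top-k genes with the single
   Gaussian kernel (mode G), cluster, and
2. compute Pillai's trace of the clustering against the embedding;
   k1 = argmax over the grid (ties -> smallest k);
3. prune: k2 = 1 + max{k < k1 : NMI(y(V_k), y(V_k1)) < 0.95}, found by a
   downward integer scan (grid-localized first when k1 is large);
4. adequacy: if NMI(y^G(V_k2), y^M(X)) > 0.7 output the mode-G result,
   otherwise rerun steps 1-3 with the learned multi-kernel similarity
   (mode M) and output that result.

Every evaluation is cached by (mode, k) and seeded deterministically from
the run seed, so a full run is a pure function of (X, C, config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import (
    ExpressionMatrix,
    FeatureSubset,
    LabelVector,
    ParameterError,
    RunConfig,
    child_seed,
)
from .embedding import (
    LatentProjection,
    kmeans_cluster,
    similarity_to_affinities,
    tsne_embed,
)
from .metrics import nmi, pillai_trace
from .scores import ScoreVector, kc_score, laplacian_score, rank_features
from .similarity import simlr_similarity, single_kernel_similarity


class DegenerateSubsetError(ValueError):
    """Raised when a candidate feature subset cannot support a similarity."""


@dataclass(frozen=True)
class SubsetEvaluation:
    """One (mode, k) evaluation: embedding, clustering and Pillai's trace."""

    k: int
    mode: str
    Z: LatentProjection
    labels: LabelVector
    pillai: float


@dataclass
class StrategyResult:
    """Full output of a selection run."""

    score_method: str
    mode_used: str
    k1: int
    k2: int
    subset: FeatureSubset
    selected_gene_ids: list
    labels: LabelVector
    reference_labels: LabelVector   # all-features multi-kernel clustering y^M(X)
    adequacy_nmi: float
    k2_flags: dict
    trace: list                      # [(mode, k, pillai), ...] in eval order
    scores: ScoreVector
    kernel_weights: list
    config: RunConfig

    def to_dict(self) -> dict:
        return {
            "score_method": self.score_method,
            "mode_used": self.mode_used,
            "k1": int(self.k1),
            "k2": int(self.k2),
            "selected_gene_ids": list(self.selected_gene_ids),
            "selected_indices": [int(i) for i in self.subset.indices],
            "labels": [int(v) for v in self.labels.labels],
            "reference_labels": [int(v) for v in self.reference_labels.labels],
            "adequacy_nmi": float(self.adequacy_nmi),
            "k2_flags": {k: bool(v) for k, v in self.k2_flags.items()},
            "trace": [[m, int(k), float(f)] for (m, k, f) in self.trace],
            "kernel_weights": [float(w) for w in self.kernel_weights],
            "config": {
                "n_clusters": self.config.n_clusters,
                "latent_dim": self.config.latent_dim,
                "seed": self.config.seed,
                "prune_nmi": self.config.prune_nmi,
                "adequacy_nmi": self.config.adequacy_nmi,
                "single_k": self.config.single_k,
                "single_sigma": self.config.single_sigma,
            },
        }


def make_k_grid(p: int, dense_k_max: int = 50, n_log_grid: int = 40) -> tuple:
    """Subset sizes to sweep: all integers 2..dense_k_max plus log-spaced
    points up to p (always including p)."""
    if p < 2:
        raise ParameterError("need at least 2 genes to sweep subsets")
    dense = list(range(2, min(dense_k_max, p) + 1))
    if p > dense_k_max and n_log_grid > 0:
        logs = np.unique(
            np.round(
                np.exp(np.linspace(np.log(dense_k_max + 1), np.log(p), n_log_grid))
            ).astype(int)
        )
        dense.extend(int(k) for k in logs if k > dense_k_max)
    if dense[-1] != p:
        dense.append(p)
    return tuple(dense)


def evaluate_subset(X: ExpressionMatrix, order, k: int, mode: str, C: int,
                    config: RunConfig, cache: dict | None = None) -> SubsetEvaluation:
    """Embed and cluster the top-k genes of the ordering in the given kernel
    mode, and compute Pillai's trace.  Deterministic given config.seed;
    cached by (mode, k)."""
    key = (mode, k)
    if cache is not None and key in cache:
        return cache[key]
    if mode not in ("G", "M"):
        raise ParameterError("mode must be 'G' or 'M'")
    order = np.asarray(order, dtype=int)
    if not 1 <= k <= order.size:
        raise ParameterError(f"k={k} out of range [1, {order.size}]")
    sub = X.values[:, order[:k]]
    if np.all(np.ptp(sub, axis=0) == 0):
        raise DegenerateSubsetError(
            f"all columns of the size-{k} subset are constant"
        )
    if mode == "G":
        S = single_kernel_similarity(sub, k=config.single_k,
                                     sigma=config.single_sigma)
    else:
        S = simlr_similarity(
            sub, C, beta=config.simlr_beta, gamma=config.simlr_gamma,
            rho=config.simlr_rho, max_iter=config.simlr_max_iter,
            tol=config.simlr_tol, k_grid=config.kernel_k_grid,
            sigma_grid=config.kernel_sigma_grid,
        ).S
    P = similarity_to_affinities(S)
    Z = tsne_embed(
        P, d=config.latent_dim, seed=child_seed(config.seed, "tsne", mode, k),
        n_iter=config.tsne_iters, learning_rate=config.tsne_learning_rate,
        early_exaggeration=config.tsne_early_exaggeration,
        provenance={"mode": mode, "k": k},
    )
    y = kmeans_cluster(Z, C, restarts=config.kmeans_restarts,
                       seed=child_seed(config.seed, "kmeans", mode, k))
    ev = SubsetEvaluation(k=k, mode=mode, Z=Z, labels=y,
                          pillai=pillai_trace(Z, y))
    if cache is not None:
        cache[key] = ev
    return ev


def find_k1(evaluations) -> int:
    """Grid size with maximal Pillai's trace; ties resolve to the smallest k."""
    evs = sorted(evaluations, key=lambda e: e.k)
    if len(evs) < 2:
        raise ParameterError("need at least 2 grid evaluations")
    best = evs[0]
    for e in evs[1:]:
        if e.pillai > best.pillai:
            best = e
    if all(e.pillai == 0 for e in evs):
        warnings.warn("Pillai's trace is zero on the whole grid", stacklevel=2)
    return best.k


def _scan_k2(nmi_at, k1: int, threshold: float = 0.95, cap: int = 500,
             grid=()) -> tuple:
    """Locate k2 = 1 + max{k < k1 : NMI(k) < threshold}.

    ``nmi_at(k)`` must return the NMI between the k-subset clustering and
    the k1-subset clustering (and may return -inf for unevaluable k).
    Scans integer-by-integer downward from k1-1; when k1-1 exceeds ``cap``
    the drop is first localized on the grid and then refined integer-wise
    inside the bracketing interval.  Returns (k2, flags) where flags mark
    the k2=1 boundary convention and an exhausted scan budget.
    """
    flags = {"boundary": False, "budget_exhausted": False}
    evals = 0

    def probe(k):
        nonlocal evals
        evals += 1
        return nmi_at(k)

    if k1 - 1 <= cap:
        for k in range(k1 - 1, 0, -1):
            if probe(k) < threshold:
                return k + 1, flags
        flags["boundary"] = True
        return 1, flags

    pts = sorted({int(g) for g in grid if 2 <= g < k1}, reverse=True)
    upper = k1 - 1
    for g in pts:
        if evals >= cap:
            flags["budget_exhausted"] = True
            return upper + 1, flags
        if probe(g) < threshold:
            for k in range(upper, g, -1):
                if evals >= cap:
                    flags["budget_exhausted"] = True
                    return k + 1, flags
                if probe(k) < threshold:
                    return k + 1, flags
            return g + 1, flags
        upper = g - 1
    low = pts[-1] if pts else 2
    for k in range(low - 1, 0, -1):
        if evals >= cap:
            flags["budget_exhausted"] = True
            return k + 1, flags
        if probe(k) < threshold:
            return k + 1, flags
    flags["boundary"] = True
    return 1, flags


def prune_to_k2(X, order, k1: int, mode: str, C: int, config: RunConfig,
                cache: dict, grid=()) -> tuple:
    """Step-3 pruning against the k1-subset clustering.

    A subset size whose evaluation fails (degenerate one-gene geometry,
    typically k=1) counts as "below threshold": its clustering cannot
    reproduce the k1 clustering.
    """
    y_ref = evaluate_subset(X, order, k1, mode, C, config, cache).labels

    def nmi_at(k):
        try:
            e = evaluate_subset(X, order, k, mode, C, config, cache)
        except Exception:
            return -np.inf
        return nmi(e.labels, y_ref)

    return _scan_k2(nmi_at, k1, threshold=config.prune_nmi,
                    cap=config.prune_cap, grid=grid)


def strategy_a(X: ExpressionMatrix, C: int, score_method: str = "kc",
               config: RunConfig | None = None) -> StrategyResult:
    """Run the full selection pipeline and return the selected genes, the
    final clustering and the evaluation trace."""
    if score_method not in ("kc", "laplacian"):
        raise ParameterError("score_method must be 'kc' or 'laplacian'")
    cfg = config if config is not None else RunConfig(n_clusters=C)
    if cfg.n_clusters != C:
        cfg = RunConfig(**{**cfg.__dict__, "n_clusters": C})

    # step 0: the multi-kernel view of the full data, computed once
    try:
        state = simlr_similarity(
            X, C, beta=cfg.simlr_beta, gamma=cfg.simlr_gamma,
            rho=cfg.simlr_rho, max_iter=cfg.simlr_max_iter, tol=cfg.simlr_tol,
            k_grid=cfg.kernel_k_grid, sigma_grid=cfg.kernel_sigma_grid,
        )
    except Exception as e:
        raise RuntimeError("similarity learning on the full data failed") from e
    P = similarity_to_affinities(state.S)
    Zm = tsne_embed(
        P, d=cfg.latent_dim, seed=child_seed(cfg.seed, "tsne", "M", 0),
        n_iter=cfg.tsne_iters, learning_rate=cfg.tsne_learning_rate,
        early_exaggeration=cfg.tsne_early_exaggeration,
        provenance={"mode": "M", "k": X.p},
    )
    ym = kmeans_cluster(Zm, C, restarts=cfg.kmeans_restarts,
                        seed=child_seed(cfg.seed, "kmeans", "M", 0))

    if score_method == "kc":
        sv = kc_score(Zm, X, rank_ladder=cfg.frk_rank_ladder,
                      correlation=cfg.score_correlation)
    else:
        sv = laplacian_score(state.S, X)
    order = rank_features(sv, X.p).indices

    cache: dict = {}
    # the full-data multi-kernel evaluation is reused as the k = p, mode-M entry
    cache[("M", X.p)] = SubsetEvaluation(
        k=X.p, mode="M", Z=Zm, labels=ym, pillai=pillai_trace(Zm, ym)
    )
    grid = make_k_grid(X.p, cfg.dense_k_max, cfg.n_log_grid)

    def steps_1_to_3(mode):
        evals = [evaluate_subset(X, order, k, mode, C, cfg, cache) for k in grid]
        k1 = find_k1(evals)
        k2, flags = prune_to_k2(X, order, k1, mode, C, cfg, cache, grid=grid)
        return k1, k2, flags

    k1, k2, flags = steps_1_to_3("G")
    final_g = evaluate_subset(X, order, max(k2, 1), "G", C, cfg, cache)
    adequacy = nmi(final_g.labels, ym)

    if adequacy > cfg.adequacy_nmi:
        mode_used, final = "G", final_g
    else:
        k1, k2, flags = steps_1_to_3("M")
        mode_used = "M"
        final = evaluate_subset(X, order, max(k2, 1), "M", C, cfg, cache)

    subset = FeatureSubset(order[: max(k2, 1)])
    trace = [(m, k, cache[(m, k)].pillai) for (m, k) in sorted(cache.keys())]
    return StrategyResult(
        score_method=score_method,
        mode_used=mode_used,
        k1=k1,
        k2=k2,
        subset=subset,
        selected_gene_ids=[X.gene_ids[i] for i in subset.indices],
        labels=final.labels,
        reference_labels=ym,
        adequacy_nmi=float(adequacy),
        k2_flags=flags,
        trace=trace,
        scores=sv,
        kernel_weights=list(map(float, state.w)),
        config=cfg,
    )
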