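"""Unsupervised feature-importance scores and ranking.

Two scores are provided:

* the Laplacian Score of a feature x against a similarity matrix S,

      L = x~' (D - S) x~ / (x~' D x~),   D = diag(S 1),
      x~ = x - (x' D 1 / 1' D 1) 1,

  where SMALLER is more important (the feature varies smoothly over the
  similarity graph); and

* the Kriging-Correlation (KC) score, the Pearson correlation between a
  feature and its reconstruction from the latent embedding via the
  fixed-rank kriging fit, where LARGER is more important.

Degenerate features (zero variance, or a zero-variance reconstruction) get
sentinel scores (+inf for Laplacian, -inf for KC) plus a flag, so that
whole-matrix scoring never aborts and such features always rank last.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import ExpressionMatrix, FeatureSubset, ParameterError
from .embedding import LatentProjection
from .kriging import BasisMatrix, default_rank_ladder, frk_fit, mrts_basis
from .similarity import SimilarityMatrix


@dataclass(frozen=True)
class ScoreVector:
    """Per-feature importance scores with ranking direction."""

    scores: np.ndarray
    method: str                  # "kc" or "laplacian"
    direction: str               # "descending" or "ascending"
    degenerate: np.ndarray       # boolean flag per feature

    @property
    def p(self) -> int:
        return self.scores.size


def laplacian_score(S: SimilarityMatrix, X: ExpressionMatrix) -> ScoreVector:
    """Laplacian Score of every gene against the similarity S (ascending)."""
    V = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, float)
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    if V.shape[0] != Xv.shape[0]:
        raise ParameterError("similarity and expression disagree on n")
    dvec = V.sum(axis=1)
    if np.any(dvec <= 0):
        raise ParameterError("similarity has a nonpositive row sum")
    dtot = dvec.sum()
    center = (Xv.T @ dvec) / dtot           # x' D 1 / 1' D 1 per gene
    Xc = Xv - center[None, :]
    den = np.einsum("ij,i,ij->j", Xc, dvec, Xc)      # x~' D x~
    num = den - np.einsum("ij,ij->j", Xc, V @ Xc)    # x~' (D - S) x~
    degenerate = den <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(degenerate, np.inf, num / np.where(degenerate, 1.0, den))
    scores = np.where(degenerate, np.inf, np.maximum(scores, 0.0))
    return ScoreVector(scores, method="laplacian", direction="ascending",
                       degenerate=degenerate)


def kc_score(Z: LatentProjection, X: ExpressionMatrix,
             rank_ladder=None, correlation: str = "pearson",
             basis: BasisMatrix | None = None) -> ScoreVector:
    """KC score of every gene: correlation of the gene with its fixed-rank
    kriging reconstruction from the latent coordinates (descending).

    The thin-plate basis is evaluated once at the maximal ladder rank and
    the nested orthonormal structure reused across genes.
    """
    Xv = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    coords = Z.coords if isinstance(Z, LatentProjection) else np.asarray(Z, float)
    n, p = Xv.shape
    if coords.shape[0] != n:
        raise ParameterError("latent projection and expression disagree on n")
    d = coords.shape[1]
    ladder = tuple(rank_ladder) if rank_ladder is not None else default_rank_ladder(n, d)
    if basis is None:
        basis = mrts_basis(coords, K=max(ladder))
    if correlation not in ("pearson", "spearman"):
        raise ParameterError("correlation must be 'pearson' or 'spearman'")

    scores = np.empty(p)
    degenerate = np.zeros(p, dtype=bool)
    for j in range(p):
        x = Xv[:, j]
        fit = frk_fit(basis, x, rank_ladder=ladder)
        if fit.degenerate or np.std(fit.fitted) == 0 or np.std(x) == 0:
            scores[j] = -np.inf
            degenerate[j] = True
            continue
        if correlation == "pearson":
            r = float(np.corrcoef(x, fit.fitted)[0, 1])
        else:
            r = float(stats.spearmanr(x, fit.fitted).statistic)
        if not np.isfinite(r):
            scores[j] = -np.inf
            degenerate[j] = True
        else:
            scores[j] = float(np.clip(r, -1.0, 1.0))
    return ScoreVector(scores, method="kc", direction="descending",
                       degenerate=degenerate)


def rank_features(scores: ScoreVector, k: int) -> FeatureSubset:
    """Top-k features by the method's direction.

    Degenerate-flagged features rank last; ties break by original gene
    index (stable).
    """
    p = scores.p
    if not 1 <= k <= p:
        raise ParameterError(f"k={k} must lie in [1, {p}]")
    key = scores.scores.copy().astype(float)
    if scores.direction == "descending":
        key = -key
    # push degenerate features past every finite score
    key = np.where(scores.degenerate, np.inf, key)
    order = np.argsort(key, kind="stable")
    return FeatureSubset(order[:k])
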