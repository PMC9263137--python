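"""Latent-space projection and clustering.

t-SNE here consumes a precomputed joint-probability matrix built from a
row-stochastic similarity (no perplexity re-estimation), mirroring how a
learned cell-cell similarity drives the embedding.  The optimizer is the
standard Kullback-Leibler gradient descent with early exaggeration,
momentum switching and per-coordinate gains; it is deterministic given a
seed.  Clustering is k-means with restarts on the latent coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .data import LabelVector, ParameterError, child_seed
from .similarity import SimilarityMatrix

_EPS = 1e-12


@dataclass(frozen=True)
class LatentProjection:
    """n × d latent coordinates with provenance metadata."""

    coords: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", c)
        if c.ndim != 2:
            raise ParameterError("latent coordinates must be 2-D (n × d)")
        if c.shape[1] not in (1, 2, 3):
            raise ParameterError("latent dimension must be 1, 2 or 3")
        if not np.all(np.isfinite(c)):
            raise ParameterError("latent coordinates must be finite")

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


def similarity_to_affinities(S: SimilarityMatrix | np.ndarray) -> np.ndarray:
    """Joint probabilities P = (S + S') / (2n), diagonal zeroed, renormalized.

    For a row-stochastic S the result is symmetric, nonnegative and sums
    to 1.
    """
    V = S.values if isinstance(S, SimilarityMatrix) else np.asarray(S, float)
    if np.any(V.sum(axis=1) <= 0):
        raise ParameterError("similarity has an all-zero row; cannot symmetrize")
    n = V.shape[0]
    P = (V + V.T) / (2.0 * n)
    np.fill_diagonal(P, 0.0)
    total = P.sum()
    if total <= 0:
        raise ParameterError("degenerate similarity: off-diagonal mass is zero")
    return P / total


def _kl(P: np.ndarray, Q: np.ndarray) -> float:
    mask = P > 0
    return float(np.sum(P[mask] * np.log(P[mask] / np.maximum(Q[mask], _EPS))))


def _student_q(Y: np.ndarray):
    num = 1.0 / (1.0 + squareform(pdist(Y, "sqeuclidean")))
    np.fill_diagonal(num, 0.0)
    return num / num.sum(), num


def tsne_embed(P: np.ndarray, d: int = 2, seed: int = 0, n_iter: int = 1000,
               learning_rate: float | str = "auto",
               early_exaggeration: float = 12.0,
               exaggeration_iters: int = 250,
               provenance: dict | None = None) -> LatentProjection:
    """Embed n points in d dimensions from joint probabilities P.

    ``learning_rate="auto"`` uses max(n / early_exaggeration / 4, 50); a
    too-large step scatters points across cluster boundaries during the
    exaggeration phase.  Returns a projection whose provenance records the
    initial and final KL divergence; the final KL never exceeds the initial
    one on any input the optimizer accepts (descent from a small random
    initialization).
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if n < 5:
        raise ParameterError("t-SNE needs at least 5 points")
    if d not in (1, 2, 3):
        raise ParameterError("latent dimension must be 1, 2 or 3")
    P = np.maximum(P, 0.0)
    P = P / P.sum()
    if learning_rate == "auto":
        learning_rate = max(n / early_exaggeration / 4.0, 50.0)

    rng = np.random.default_rng(seed)
    Y = 1e-4 * rng.standard_normal((n, d))
    dY = np.zeros_like(Y)
    gains = np.ones_like(Y)

    Q0, _ = _student_q(Y)
    kl_initial = _kl(P, Q0)

    for it in range(n_iter):
        exag = early_exaggeration if it < exaggeration_iters else 1.0
        Q, num = _student_q(Y)
        PQ = (exag * P - Q) * num
        # gradient of KL wrt Y (factor 4 of the standard derivation)
        grad = 4.0 * ((np.diag(PQ.sum(axis=1)) - PQ) @ Y)
        momentum = 0.5 if it < exaggeration_iters else 0.8
        inc = np.sign(grad) != np.sign(dY)
        gains = np.where(inc, gains + 0.2, gains * 0.8)
        gains = np.maximum(gains, 0.01)
        dY = momentum * dY - learning_rate * gains * grad
        Y = Y + dY
        Y = Y - Y.mean(axis=0)

    Qf, _ = _student_q(Y)
    kl_final = _kl(P, Qf)
    prov = dict(provenance or {})
    prov.update(seed=seed, kl_initial=kl_initial, kl_final=kl_final)
    return LatentProjection(Y, prov)


def kmeans_cluster(Z: LatentProjection | np.ndarray, C: int,
                   restarts: int = 50, seed: int = 0) -> LabelVector:
    """k-means with k-means++ restarts; labels are 1-based.

    The best inertia over ``restarts`` initializations is kept; the result
    is deterministic given the seed.
    """
    coords = Z.coords if isinstance(Z, LatentProjection) else np.asarray(Z, float)
    n = coords.shape[0]
    if C > n:
        raise ParameterError(f"C={C} clusters exceed n={n} points")
    if C < 1:
        raise ParameterError("C must be >= 1")
    km = KMeans(
        n_clusters=C, n_init=restarts, init="k-means++",
        random_state=child_seed(seed, "kmeans"),
    ).fit(coords)
    return LabelVector(km.labels_.astype(int) + 1, C)
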