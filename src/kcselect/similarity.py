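"""Cell-cell similarity construction.

Two routes are provided, mirroring the two kernel modes of the selection
pipeline:

* a single locally-scaled Gaussian kernel, symmetrized and row-normalized
  (mode "G"); and
* a multi-kernel similarity learned by alternating minimization of the
  SIMLR-style objective (mode "M"):

      min_{S,L,w}  sum_ij D(x_i, x_j) S_ij + beta ||S||_F^2
                   + gamma tr(L' (I - S) L) + rho sum_l w_l log w_l

  subject to D(x_i, x_j) = sum_l w_l [K_l(i,i) + K_l(j,j) - 2 K_l(i,j)],
  w on the probability simplex, L'L = I_C, and S row-stochastic nonnegative.

Each kernel in the bank is a locally-scaled Gaussian

    K_k^sigma(x_i, x_j) = exp(-||x_i - x_j||^2 / (sigma^2 (s_i + s_j)))
                          / (sigma (s_i + s_j) sqrt(2 pi)),

where s_i is the mean Euclidean distance from cell i to its k nearest
neighbors.  The bank spans k in {10, 12, ..., 30} and sigma in
{1.0, 1.25, ..., 2.0} — 55 kernels on full grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import (
    DegenerateGeometryError,
    ExpressionMatrix,
    ParameterError,
)

_SQRT_2PI = np.sqrt(2.0 * np.pi)

DEFAULT_K_GRID = tuple(range(10, 31, 2))
DEFAULT_SIGMA_GRID = (1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass(frozen=True)
class KernelMatrix:
    """A symmetric nonnegative kernel evaluation with its (k, sigma) params."""

    values: np.ndarray
    k: int
    sigma: float


@dataclass(frozen=True)
class SimilarityMatrix:
    """Row-stochastic nonnegative n × n similarity.

    ``mode`` records provenance: "G" for single Gaussian kernel, "M" for the
    learned multi-kernel similarity (which also carries kernel weights).
    """

    values: np.ndarray
    mode: str
    kernel_weights: np.ndarray | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("similarity must be square")
        if np.any(v < -1e-12):
            raise ParameterError("similarity entries must be nonnegative")
        rs = v.sum(axis=1)
        if np.max(np.abs(rs - 1.0)) > 1e-8:
            raise ParameterError("similarity rows must sum to 1 (tol 1e-8)")
        if self.mode not in ("G", "M"):
            raise ParameterError("mode must be 'G' or 'M'")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SimlrState:
    """Converged (or best-effort) state of the multi-kernel optimization."""

    S: SimilarityMatrix
    L: np.ndarray                       # n × C, column-orthonormal
    w: np.ndarray                       # kernel weights on the simplex
    objective: np.ndarray               # value after each outer iteration
    kernel_params: list                 # [(k, sigma), ...] aligned with w
    converged: bool
    # per-iteration invariant diagnostics (max deviations)
    row_sum_dev: np.ndarray = field(default_factory=lambda: np.array([]))
    simplex_dev: np.ndarray = field(default_factory=lambda: np.array([]))


def _as_values(X) -> np.ndarray:
    return X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)


def _pairwise_sq(values: np.ndarray) -> np.ndarray:
    d2 = squareform(pdist(values, metric="sqeuclidean"))
    return np.maximum(d2, 0.0)


def local_scales(X, k: int) -> np.ndarray:
    """Mean Euclidean distance from each cell to its k nearest neighbors.

    Duplicate points may yield a zero scale; that is legal here and only
    becomes an error (or is floored) at kernel construction.
    """
    values = _as_values(X)
    n = values.shape[0]
    if not 1 <= k <= n - 1:
        raise ParameterError(f"neighbor count k={k} must lie in [1, n-1]={n - 1}")
    d = np.sqrt(_pairwise_sq(values))
    np.fill_diagonal(d, np.inf)  # exclude self
    part = np.partition(d, k - 1, axis=1)[:, :k]
    return part.mean(axis=1)


def _resolve_scales(sig: np.ndarray, zero_scale: str) -> np.ndarray:
    """Apply the zero-local-scale policy; returns strictly positive scales
    under "floor", raw scales under "error"."""
    if zero_scale not in ("error", "floor"):
        raise ParameterError("zero_scale must be 'error' or 'floor'")
    if zero_scale == "floor" and np.any(sig == 0):
        pos = sig[sig > 0]
        if pos.size == 0:
            raise DegenerateGeometryError(
                "all local scales are zero (all cells identical)"
            )
        sig = np.maximum(sig, 1e-3 * pos.mean())
    return sig


def gaussian_kernel(X, k: int, sigma: float, zero_scale: str = "error") -> KernelMatrix:
    """Locally-scaled Gaussian kernel matrix.

    ``zero_scale`` controls duplicate-point geometry: "error" (default)
    raises naming the offending pair; "floor" replaces zero local scales by
    1e-3 × the mean positive scale so pipelines survive exact-duplicate
    cells (common with dropout-dominated subsets).
    """
    values = _as_values(X)
    sig = local_scales(values, k)
    if zero_scale == "error":
        zero = np.flatnonzero(sig == 0)
        if zero.size >= 2:
            i, j = int(zero[0]), int(zero[1])
            raise DegenerateGeometryError(
                f"local scales of cells {i} and {j} are both zero "
                "(duplicate points); sigma_i + sigma_j = 0"
            )
    sig = _resolve_scales(sig, zero_scale)
    ssum = sig[:, None] + sig[None, :]
    if np.any(ssum == 0):
        i, j = np.argwhere(ssum == 0)[0]
        raise DegenerateGeometryError(
            f"sigma_{i} + sigma_{j} = 0: degenerate geometry for pair ({i}, {j})"
        )
    d2 = _pairwise_sq(values)
    K = np.exp(-d2 / (sigma**2 * ssum)) / (sigma * ssum * _SQRT_2PI)
    K = 0.5 * (K + K.T)  # exact symmetry against float noise
    return KernelMatrix(K, k=k, sigma=float(sigma))


def kernel_bank(X, k_grid=None, sigma_grid=None, zero_scale: str = "floor"):
    """Evaluate the Gaussian kernel over the (k, sigma) grid.

    Full grids give 55 kernels.  When n <= max(k_grid) the neighbor grid is
    truncated to valid values (k <= n-1) with a warning.
    """
    values = _as_values(X)
    n = values.shape[0]
    k_grid = tuple(DEFAULT_K_GRID if k_grid is None else k_grid)
    sigma_grid = tuple(DEFAULT_SIGMA_GRID if sigma_grid is None else sigma_grid)
    valid = tuple(k for k in k_grid if k <= n - 1)
    if valid != k_grid:
        warnings.warn(
            f"neighbor grid truncated to k <= n-1 = {n - 1}: {valid}",
            stacklevel=2,
        )
    if not valid:
        raise ParameterError(f"no valid neighbor count for n={n}")
    return [
        gaussian_kernel(values, k, s, zero_scale=zero_scale)
        for k in valid
        for s in sigma_grid
    ]


def _row_normalize(M: np.ndarray) -> np.ndarray:
    rs = M.sum(axis=1, keepdims=True)
    if np.any(rs <= 0):
        raise DegenerateGeometryError("cannot row-normalize: nonpositive row sum")
    return M / rs


def single_kernel_similarity(X, k: int = 20, sigma: float = 1.5,
                             zero_scale: str = "floor") -> SimilarityMatrix:
    """Row-stochastic similarity from one Gaussian kernel (mode G).

    Construction: row-normalize the kernel, symmetrize by averaging with the
    transpose, then re-row-normalize.  Defaults (k=20, sigma=1.5) are the
    kernel-grid midpoints; k is clipped to n-1 for small inputs.
    """
    values = _as_values(X)
    n = values.shape[0]
    K = gaussian_kernel(values, min(k, n - 1), sigma, zero_scale=zero_scale)
    R = _row_normalize(K.values)
    S = _row_normalize(0.5 * (R + R.T))
    return SimilarityMatrix(S, mode="G")


# ---------------------------------------------------------------------------
# Multi-kernel (SIMLR-style) optimization
# ---------------------------------------------------------------------------


def project_rows_to_simplex(U: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row of U onto the probability simplex."""
    n, m = U.shape
    s = -np.sort(-U, axis=1)
    css = np.cumsum(s, axis=1)
    j = np.arange(1, m + 1)
    cond = s - (css - 1.0) / j > 0
    rho = m - np.argmax(cond[:, ::-1], axis=1) - 1  # last True per row
    theta = (css[np.arange(n), rho] - 1.0) / (rho + 1)
    return np.maximum(U - theta[:, None], 0.0)


def kernel_pseudo_distances(bank) -> np.ndarray:
    """Stack of kernel-induced squared feature-map distances
    d_l(i,j) = K_l(i,i) + K_l(j,j) - 2 K_l(i,j); nonnegative for the
    locally-scaled Gaussian family (clipped at 0 against float noise)."""
    out = []
    for km in bank:
        K = km.values
        diag = np.diag(K)
        d = diag[:, None] + diag[None, :] - 2.0 * K
        out.append(np.maximum(d, 0.0))
    return np.stack(out, axis=0)


def _simlr_objective(D_mix, S, L, w, beta, gamma, rho) -> float:
    wlogw = float(np.sum(np.where(w > 0, w * np.log(np.maximum(w, 1e-300)), 0.0)))
    C = L.shape[1]
    tr = C - float(np.einsum("ij,ic,jc->", S, L, L))
    return (
        float(np.sum(D_mix * S))
        + beta * float(np.sum(S * S))
        + gamma * tr
        + rho * wlogw
    )


def simlr_similarity(X, C: int, beta: float = 1.0, gamma: float = 1.0,
                     rho: float = 1.0, max_iter: int = 30, tol: float = 1e-6,
                     k_grid=None, sigma_grid=None) -> SimlrState:
    """Learn a multi-kernel similarity by block alternating minimization.

    Each block solves its subproblem exactly, so the recorded objective is
    non-increasing across outer iterations:

    * w: closed-form softmax from the entropy term's stationarity,
      w_l ∝ exp(-<d_l, S> / rho);
    * L: top-C eigenvectors of (S + S') / 2;
    * S: row-wise Euclidean projection onto the probability simplex of the
      unconstrained quadratic minimizer (gamma LL' - D) / (2 beta).

    Non-convergence after ``max_iter`` returns the best state with
    ``converged=False``.
    """
    if C < 2:
        raise ParameterError("C must be >= 2")
    values = _as_values(X)
    n = values.shape[0]
    bank = kernel_bank(values, k_grid=k_grid, sigma_grid=sigma_grid,
                       zero_scale="floor")
    D_all = kernel_pseudo_distances(bank)
    n_kernels = D_all.shape[0]

    w = np.full(n_kernels, 1.0 / n_kernels)
    # init S from the row-normalized mean kernel (row-stochastic by construction)
    K_mean = np.mean([km.values for km in bank], axis=0)
    S = _row_normalize(K_mean)

    def top_eigvecs(Ssym, C):
        evals, evecs = np.linalg.eigh(Ssym)
        return evecs[:, ::-1][:, :C]

    L = top_eigvecs(0.5 * (S + S.T), C)
    D_mix = np.tensordot(w, D_all, axes=1)
    obj = [_simlr_objective(D_mix, S, L, w, beta, gamma, rho)]
    row_dev, simp_dev = [], []

    converged = False
    for _ in range(max_iter):
        # L-step: exact minimizer over the Stiefel constraint
        L = top_eigvecs(0.5 * (S + S.T), C)
        # w-step: softmax of the per-kernel transport costs
        costs = np.tensordot(D_all, S, axes=([1, 2], [0, 1]))
        e = -(costs - costs.min()) / rho
        w = np.exp(e)
        w /= w.sum()
        D_mix = np.tensordot(w, D_all, axes=1)
        # S-step: row-wise projected quadratic minimizer
        A = L @ L.T
        S = project_rows_to_simplex((gamma * A - D_mix) / (2.0 * beta))

        val = _simlr_objective(D_mix, S, L, w, beta, gamma, rho)
        if not np.isfinite(val):
            raise FloatingPointError("non-finite objective in similarity learning")
        obj.append(val)
        row_dev.append(float(np.max(np.abs(S.sum(axis=1) - 1.0))))
        simp_dev.append(max(abs(float(w.sum()) - 1.0), float(-min(w.min(), 0.0))))
        if abs(obj[-2] - obj[-1]) <= tol * max(abs(obj[-2]), 1.0):
            converged = True
            break

    if not converged:
        warnings.warn("similarity learning did not converge; returning best state",
                      stacklevel=2)
    sim = SimilarityMatrix(_row_normalize(np.maximum(S, 0.0)), mode="M",
                           kernel_weights=w.copy())
    return SimlrState(
        S=sim, L=L, w=w, objective=np.asarray(obj),
        kernel_params=[(km.k, km.sigma) for km in bank],
        converged=converged,
        row_sum_dev=np.asarray(row_dev), simplex_dev=np.asarray(simp_dev),
    )
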