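"""Multi-resolution thin-plate spline basis and fixed-rank kriging fit.

The basis ``G`` evaluated at the n latent locations consists of a constant
column, the d coordinate columns, and eigenvector columns of the projected
thin-plate radial kernel: with Z~ = [1 Z], Q = I - Z~ (Z~'Z~)^{-1} Z~' and
Phi_ik = phi(||z_i - z_k||), the trailing columns are the leading
eigenvectors of Q Phi Q (ordered by decreasing eigenvalue).  They are
mutually orthonormal and orthogonal to [1 Z] at the training locations.

The per-feature spatial random-effect model is

    x = G w + eta,   w ~ N(0, M),   eta ~ N(0, sigma^2 I),

fit by maximum likelihood in the orthonormalized-basis coordinates: the
squared basis coefficients of the centered feature are thresholded at the
noise variance (the regularized fixed-rank MLE), and the basis count is
chosen from a rank ladder by AIC.  Features are mean-centered before the
fit and the mean added back, making the downstream correlation score
shift-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .data import DegenerateGeometryError, ParameterError
from .embedding import LatentProjection


def radial_phi(r, d: int):
    """Thin-plate radial function of the distance r in dimension d.

    d=1: r^3 / 12;  d=2: r^2 log(r) / (8 pi);  d=3: -r / 8.
    The d=2 removable singularity at r=0 is defined as 0.
    """
    if d not in (1, 2, 3):
        raise ParameterError("dimension d must be 1, 2 or 3")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ParameterError("distances must be nonnegative")
    if d == 1:
        out = r**3 / 12.0
    elif d == 2:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r > 0, r**2 * np.log(np.maximum(r, 1e-300)) / (8.0 * np.pi), 0.0)
    else:
        out = -r / 8.0
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class BasisMatrix:
    """Multi-resolution thin-plate spline basis at n training locations.

    Column 1 is all-ones, columns 2..d+1 the latent coordinates, higher
    columns the unit-norm eigenvectors described in the module docstring.
    Retains the pieces needed for nested-rank fits: the orthonormalized
    basis F and the triangular factor linking F to G.
    """

    G: np.ndarray                 # n × K
    Z: np.ndarray                 # n × d training locations
    lambdas: np.ndarray           # K-(d+1) eigenvalues, decreasing
    F: np.ndarray                 # n × K, orthonormal columns, span(G) = span(F)
    R: np.ndarray                 # K × K upper-triangular with G = F R

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def K(self) -> int:
        return self.G.shape[1]

    @property
    def d(self) -> int:
        return self.Z.shape[1]


def mrts_basis(Z, K: int | None = None) -> BasisMatrix:
    """Evaluate the multi-resolution thin-plate spline basis at Z.

    Parameters
    ----------
    Z : LatentProjection or (n, d) array of locations.
    K : basis count, d+1 <= K <= n-1 (default n-1, capped at the number of
        numerically positive eigenvalues of the projected kernel).
    """
    coords = Z.coords if isinstance(Z, LatentProjection) else np.asarray(Z, float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n, d = coords.shape
    if d not in (1, 2, 3):
        raise ParameterError("location dimension must be 1, 2 or 3")
    if K is None:
        K = n - 1
    if not d + 1 <= K <= n:
        raise ParameterError(f"basis count K={K} must lie in [{d + 1}, {n}]")

    Zt = np.column_stack([np.ones(n), coords])
    Qz, Rz = np.linalg.qr(Zt)
    if np.min(np.abs(np.diag(Rz))) < 1e-10 * max(1.0, np.max(np.abs(Rz))):
        raise DegenerateGeometryError(
            "[1 Z] is rank deficient (e.g. all cells at one location)"
        )

    r = cdist(coords, coords)
    Phi = radial_phi(r, d)
    H = Qz @ Qz.T
    QPhiQ = Phi - H @ Phi - Phi @ H + H @ (Phi @ H)
    QPhiQ = 0.5 * (QPhiQ + QPhiQ.T)
    evals, evecs = np.linalg.eigh(QPhiQ)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    m = K - (d + 1)
    if m > 0:
        scale = max(abs(evals[0]), 1.0)
        if evals[m - 1] <= 1e-12 * scale:
            raise ParameterError(
                f"only {int(np.sum(evals > 1e-12 * scale))} well-conditioned "
                f"eigen columns are available; requested {m}"
            )
    lambdas = evals[:m]
    V = evecs[:, :m]
    # resolve the eigenvector sign ambiguity deterministically
    for j in range(m):
        col = V[:, j]
        lead = col[np.argmax(np.abs(col))]
        if lead < 0:
            V[:, j] = -col

    G = np.column_stack([Zt, V])
    F = np.column_stack([Qz, V])
    R = np.zeros((K, K))
    R[: d + 1, : d + 1] = Rz
    if m > 0:
        R[d + 1 :, d + 1 :] = np.eye(m)
    return BasisMatrix(G=G, Z=coords, lambdas=lambdas, F=F, R=R)


def default_rank_ladder(n: int, d: int) -> tuple:
    """Candidate basis counts {d+1, ceil(n/8), ceil(n/4), ceil(n/2), n-1},
    clipped to [d+1, n-1]."""
    raw = {d + 1, -(-n // 8), -(-n // 4), -(-n // 2), n - 1}
    return tuple(sorted(k for k in raw if d + 1 <= k <= n - 1))


@dataclass(frozen=True)
class FrkFit:
    """Result of the per-feature spatial random-effect fit."""

    fitted: np.ndarray            # n-vector x-hat
    w_hat: np.ndarray             # posterior-mean random effects (K-vector)
    M_hat: np.ndarray             # K × K PSD covariance estimate (G coordinates)
    sigma2: float                 # noise variance estimate >= 0
    mu: float                     # feature mean added back after the centered fit
    rank: int                     # basis count selected by AIC
    degenerate: bool              # zero-variance feature: fit undefined


def _regularized_mle(a: np.ndarray, r2: float, n: int, K: int):
    """Threshold MLE of (m, sigma^2) given basis coefficients a and residual
    squared norm r2 over n - K complementary directions.

    Minimizes (n-K) log s2 + r2/s2 + sum_j [log(m_j + s2) + a_j^2/(m_j + s2)]
    over m_j >= 0, s2 > 0: m_j = max(a_j^2 - s2, 0) and s2 the mean of the
    residual plus sub-threshold coefficient energy.
    """
    a2 = a**2
    total = r2 + a2.sum()
    floor = max(1e-12 * total / max(n, 1), 1e-300)
    s2 = max(total / n, floor)
    for _ in range(200):
        below = a2 <= s2
        denom = (n - K) + int(below.sum())
        s2_new = (r2 + a2[below].sum()) / denom if denom > 0 else floor
        s2_new = max(s2_new, floor)
        if abs(s2_new - s2) <= 1e-14 * max(s2, 1e-300):
            s2 = s2_new
            break
        s2 = s2_new
    m = np.maximum(a2 - s2, 0.0)
    nll = 0.5 * (
        (n - K) * np.log(s2)
        + r2 / s2
        + np.sum(np.log(m + s2) + a2 / (m + s2))
    )
    return m, float(s2), float(nll)


def frk_fit(G: BasisMatrix, x, rank_ladder=None) -> FrkFit:
    """Fit the spatial random-effect model to one feature and return the
    posterior-mean reconstruction.

    The basis count is selected from ``rank_ladder`` (default
    :func:`default_rank_ladder`) by AIC with one parameter per retained
    random-effect direction plus the noise variance; ties prefer the
    smaller rank.
    """
    x = np.asarray(x, dtype=float)
    n = G.n
    if x.shape != (n,):
        raise ParameterError(f"feature must have length n={n}")
    if not np.all(np.isfinite(x)):
        raise ParameterError("feature contains non-finite values")
    if rank_ladder is None:
        ladder = tuple(k for k in default_rank_ladder(n, G.d) if k <= G.K)
        ladder = ladder or (G.K,)
    else:
        ladder = tuple(rank_ladder)
    ladder = tuple(sorted(set(int(k) for k in ladder)))
    if not ladder or ladder[0] < G.d + 1 or ladder[-1] > G.K:
        raise ParameterError(
            f"rank ladder must lie in [{G.d + 1}, {G.K}], got {ladder}"
        )

    mu = float(x.mean())
    xc = x - mu
    xnorm2 = float(xc @ xc)
    if xnorm2 == 0.0:
        K0 = ladder[0]
        return FrkFit(
            fitted=np.full(n, mu), w_hat=np.zeros(K0),
            M_hat=np.zeros((K0, K0)), sigma2=0.0, mu=mu, rank=K0,
            degenerate=True,
        )

    a_full = G.F.T @ xc  # coefficients in the orthonormal basis
    best = None
    for K in ladder:
        a = a_full[:K]
        r2 = max(xnorm2 - float(a @ a), 0.0)
        m, s2, nll = _regularized_mle(a, r2, n, K)
        aic = 2.0 * nll + 2.0 * (int(np.sum(m > 0)) + 1)
        if best is None or aic < best[0] - 1e-12:
            best = (aic, K, m, s2)
    _, K, m, s2 = best

    a = a_full[:K]
    shrink = m / (m + s2) if s2 > 0 else np.ones_like(m)
    coef = shrink * a                      # F-coordinates of the fit
    fitted = mu + G.F[:, :K] @ coef

    # convert to the raw-basis parameterization G = F R
    RK = G.R[:K, :K]
    Rinv = np.linalg.inv(RK)
    M_hat = Rinv @ np.diag(m) @ Rinv.T
    w_hat = Rinv @ coef
    return FrkFit(
        fitted=fitted, w_hat=w_hat, M_hat=0.5 * (M_hat + M_hat.T),
        sigma2=s2, mu=mu, rank=K, degenerate=False,
    )


def frk_predict(G: np.ndarray, M: np.ndarray, sigma2: float, x,
                mu: float | None = None) -> np.ndarray:
    """Posterior-mean fitted values for a FIXED (M, sigma^2):

        x-hat = mu + G M G' (G M G' + sigma^2 I)^{-1} (x - mu).

    Direct dense computation; useful for cross-checking the fit path.
    """
    x = np.asarray(x, dtype=float)
    G = np.asarray(G, dtype=float)
    mu = float(x.mean()) if mu is None else float(mu)
    C = G @ M @ G.T
    n = C.shape[0]
    return mu + C @ np.linalg.solve(C + sigma2 * np.eye(n), x - mu)
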