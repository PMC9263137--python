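"""Evaluation statistics for clusterings and latent projections.

* NMI(U, V) = I(U, V) / max(H(U), H(V)) with natural logarithms; degenerate
  conventions: both partitions trivial -> 1, exactly one trivial -> 0.
* Pillai's trace F = tr(B (B + W)^{-1}) from the between/within SSCP
  decomposition of the latent coordinates against a label vector.
* NNA: 5-fold cross-validated 1-nearest-neighbor accuracy (Euclidean).
* RFA: 5-fold cross-validated random-forest accuracy.

Fold assignment for NNA/RFA is stratified and seeded, so both metrics are
deterministic given the seed.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import normalized_mutual_info_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .data import LabelVector, ParameterError, child_seed
from .embedding import LatentProjection


def _labels(y) -> np.ndarray:
    return y.labels if isinstance(y, LabelVector) else np.asarray(y, dtype=int)


def nmi(U, V) -> float:
    """Normalized mutual information in [0, 1] (max normalization)."""
    u, v = _labels(U), _labels(V)
    if u.size != v.size:
        raise ParameterError("label vectors must have equal length")
    pu, pv = np.unique(u).size, np.unique(v).size
    if pu == 1 and pv == 1:
        return 1.0
    if pu == 1 or pv == 1:
        return 0.0
    return float(normalized_mutual_info_score(u, v, average_method="max"))


def pillai_trace(Z, y) -> float:
    """Pillai's trace tr(B (B + W)^{-1}) of latent coordinates against labels.

    B and W are the between- and within-group sum-of-cross-products
    matrices.  A singular B + W falls back to the Moore-Penrose
    pseudo-inverse with a warning (k-means output can be collinear).
    """
    coords = Z.coords if isinstance(Z, LatentProjection) else np.asarray(Z, float)
    lab = _labels(y)
    n, d = coords.shape
    if lab.size != n:
        raise ParameterError("labels and coordinates disagree on n")
    groups = np.unique(lab)
    grand = coords.mean(axis=0)
    B = np.zeros((d, d))
    W = np.zeros((d, d))
    for g in groups:
        sel = coords[lab == g]
        if sel.shape[0] == 0:
            raise ParameterError(f"group {g} is empty")
        mg = sel.mean(axis=0)
        dg = (mg - grand)[:, None]
        B += sel.shape[0] * (dg @ dg.T)
        R = sel - mg
        W += R.T @ R
    T = B + W
    try:
        sol = np.linalg.solve(T, B)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
        cond = np.linalg.cond(T)
        if cond > 1e12:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("B + W is singular; using pseudo-inverse", stacklevel=2)
        sol = np.linalg.pinv(T) @ B
    return float(np.trace(sol))


def _fold_accuracy(coords, lab, clf_factory, folds, seed) -> float:
    n = coords.shape[0]
    if n < folds:
        raise ParameterError(f"need at least {folds} observations")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=child_seed(seed, "folds"))
    accs = []
    for f, (tr, te) in enumerate(skf.split(coords, lab)):
        if np.unique(lab[tr]).size < np.unique(lab).size:
            warnings.warn(f"fold {f} lost a class from its training split",
                          stacklevel=3)
        clf = clf_factory(f)
        clf.fit(coords[tr], lab[tr])
        accs.append(float(np.mean(clf.predict(coords[te]) == lab[te])))
    return float(np.mean(accs))


def nna(Z, y_true, folds: int = 5, seed: int = 0) -> float:
    """Nearest-neighbor accuracy: mean 5-fold CV accuracy of a 1-NN
    classifier on the latent coordinates."""
    coords = Z.coords if isinstance(Z, LatentProjection) else np.asarray(Z, float)
    lab = _labels(y_true)
    return _fold_accuracy(
        coords, lab,
        lambda f: KNeighborsClassifier(n_neighbors=1, metric="euclidean"),
        folds, seed,
    )


def rfa(Z, y_true, folds: int = 5, trees: int = 500, seed: int = 0) -> float:
    """Random-forest accuracy: mean 5-fold CV accuracy of a random forest
    on the latent coordinates."""
    coords = Z.coords if isinstance(Z, LatentProjection) else np.asarray(Z, float)
    lab = _labels(y_true)
    return _fold_accuracy(
        coords, lab,
        lambda f: RandomForestClassifier(
            n_estimators=trees, random_state=child_seed(seed, "rf", f)
        ),
        folds, seed,
    )
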