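"""Synthetic expression matrices with planted cluster structure.

Two generators cover the regimes the method targets:

* :func:`simulate_classes` — class-structured log-normal expression with a
  chosen number of informative marker genes (class-specific log-scale mean
  shifts) plus uninformative noise genes, and Bernoulli dropout masking to
  exact zero;
* :func:`simulate_dropout_pattern` — three classes that are separated
  PURELY by the dropout patterns of two diagnostic genes, the mechanism by
  which two genes can suffice for perfect clustering of hundreds of cells.

Expression is log-normal (positive, right-skewed, scRNA-like) rather than
count-based; dropout is Bernoulli masking to exact zero.  Both generators
are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, LabelVector, ParameterError


@dataclass
class SimulationSpec:
    """Conditions for the class-structured generator.

    effect_size is the log-scale mean shift of a marker gene in its elevated
    class; dispersion the log-scale standard deviation; dropout the
    Bernoulli zeroing rate.  ``informative_dropout`` optionally gives a
    per-class dropout rate for informative genes (length n_classes),
    otherwise the uniform rate applies everywhere.
    """

    n: int = 300
    p: int = 1000
    n_classes: int = 3
    n_informative: int = 20
    effect_size: float = 3.0
    dispersion: float = 0.5
    dropout: float = 0.1
    informative_dropout: tuple | None = None
    base_log_mean: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ParameterError("need at least 2 classes")
        if not 0 <= self.n_informative <= self.p:
            raise ParameterError("n_informative must lie in [0, p]")
        if not 0.0 <= self.dropout <= 1.0:
            raise ParameterError("dropout rate must lie in [0, 1]")
        if self.informative_dropout is not None:
            rates = tuple(self.informative_dropout)
            if len(rates) != self.n_classes or any(
                not 0.0 <= r <= 1.0 for r in rates
            ):
                raise ParameterError(
                    "informative_dropout needs one rate in [0,1] per class"
                )
        if self.n < self.n_classes:
            raise ParameterError("need at least one cell per class")


def _balanced_labels(n: int, G: int) -> np.ndarray:
    reps = [n // G + (1 if g < n % G else 0) for g in range(G)]
    return np.repeat(np.arange(1, G + 1), reps)


def simulate_classes(spec: SimulationSpec):
    """Generate (ExpressionMatrix, LabelVector) with planted marker genes.

    The first ``n_informative`` columns are markers: gene j is elevated by
    ``effect_size`` on the log scale in class (j mod n_classes) + 1.  The
    remaining columns are class-independent noise.  All values are then
    zeroed by Bernoulli dropout.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _balanced_labels(spec.n, spec.n_classes)

    logmean = np.full((spec.n, spec.p), spec.base_log_mean)
    for j in range(spec.n_informative):
        cls = j % spec.n_classes + 1
        logmean[labels == cls, j] += spec.effect_size
    X = np.exp(logmean + spec.dispersion * rng.standard_normal((spec.n, spec.p)))

    drop = np.full((spec.n, spec.p), spec.dropout)
    if spec.informative_dropout is not None:
        rates = np.asarray(spec.informative_dropout, dtype=float)
        drop[:, : spec.n_informative] = rates[labels - 1][:, None]
    X[rng.random((spec.n, spec.p)) < drop] = 0.0

    gene_ids = [
        f"marker{j % spec.n_classes + 1}_{j}" if j < spec.n_informative else f"noise_{j}"
        for j in range(spec.p)
    ]
    cell_ids = [f"cell_{i}" for i in range(spec.n)]
    return (
        ExpressionMatrix(X, cell_ids, gene_ids),
        LabelVector(labels, spec.n_classes),
    )


def simulate_dropout_pattern(n: int, p_noise: int = 500, seed: int = 0,
                             expressed_log_mean: float = 3.0,
                             expressed_log_sd: float = 0.25,
                             noise_log_sd: float = 0.5,
                             noise_dropout: float = 0.3):
    """Three classes separated exactly by the dropout patterns of two genes.

    Gene A is dropped (zero) in classes 1-2 and expressed in class 3; gene
    B is dropped in class 1 only.  The class partition therefore equals the
    pattern partition (0,0), (0,+), (+,+) of (A, B).  ``p_noise``
    uninformative log-normal genes with class-independent dropout are
    appended after the two diagnostic genes.
    """
    if n < 6:
        raise ParameterError("need n >= 6 to populate three classes")
    labels = _balanced_labels(n, 3)
    rng = np.random.default_rng(seed)

    def expressed(size):
        return np.exp(expressed_log_mean + expressed_log_sd * rng.standard_normal(size))

    gene_a = np.zeros(n)
    gene_a[labels == 3] = expressed(int(np.sum(labels == 3)))
    gene_b = np.zeros(n)
    gene_b[labels != 1] = expressed(int(np.sum(labels != 1)))

    noise = np.exp(noise_log_sd * rng.standard_normal((n, p_noise)))
    noise[rng.random((n, p_noise)) < noise_dropout] = 0.0

    X = np.column_stack([gene_a, gene_b, noise])
    gene_ids = ["geneA", "geneB"] + [f"noise_{j}" for j in range(p_noise)]
    cell_ids = [f"cell_{i}" for i in range(n)]
    return ExpressionMatrix(X, cell_ids, gene_ids), LabelVector(labels, 3)


def dropout_pattern_partition(X: ExpressionMatrix) -> LabelVector:
    """Partition cells by the zero/nonzero pattern of the two diagnostic
    genes (columns 0 and 1): (0,0) -> 1, (0,+) -> 2, (+,+) -> 3."""
    a = X.values[:, 0] > 0
    b = X.values[:, 1] > 0
    lab = np.where(~a & ~b, 1, np.where(~a & b, 2, 3))
    return LabelVector(lab, 3)
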