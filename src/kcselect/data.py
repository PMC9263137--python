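"""Core data containers, readers/writers and run configuration.

The package-internal orientation is always cells × genes (n observations of p
features).  Readers accept either orientation on disk and transpose on load.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse


class ParseError(ValueError):
    """Raised when an input file cannot be interpreted as an expression matrix."""


class ParameterError(ValueError):
    """Raised when an operation receives an out-of-range parameter."""


class DegenerateGeometryError(ValueError):
    """Raised when point geometry makes a kernel or basis undefined."""


def child_seed(base: int, *tokens) -> int:
    """Derive a reproducible sub-seed (< 2**31) from a base seed and a key.

    Every randomized stage of a run draws from a seed produced here, so a run
    is a pure function of (inputs, config, seed).
    """
    h = zlib.crc32(repr(tokens).encode("utf8"))
    ss = np.random.SeedSequence([int(base) & 0x7FFFFFFF, int(h)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """A cells × genes numeric expression matrix with identifiers.

    Invariants: values finite, n >= 3, p >= 1, ids unique.  Genes with zero
    variance are legal (they are flagged downstream by the score operations).
    """

    values: np.ndarray
    cell_ids: tuple
    gene_ids: tuple

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ParseError("expression values must be a 2-D matrix")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "cell_ids", tuple(str(c) for c in self.cell_ids))
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        n, p = v.shape
        if n < 3:
            raise ParseError(f"need at least 3 cells, got {n}")
        if p < 1:
            raise ParseError("need at least 1 gene")
        if len(self.cell_ids) != n or len(self.gene_ids) != p:
            raise ParseError("id lengths do not match matrix shape")
        if not np.all(np.isfinite(v)):
            i, k = np.argwhere(~np.isfinite(v))[0]
            raise ParseError(
                f"non-finite value at cell {self.cell_ids[i]!r}, gene {self.gene_ids[k]!r}"
            )
        if len(set(self.cell_ids)) != n:
            raise ParseError("duplicate cell ids")
        if len(set(self.gene_ids)) != p:
            raise ParseError("duplicate gene ids")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def subset(self, indices) -> "ExpressionMatrix":
        """Column (gene) subset, keeping the given order."""
        idx = np.asarray(indices, dtype=int)
        return ExpressionMatrix(
            self.values[:, idx],
            self.cell_ids,
            tuple(self.gene_ids[j] for j in idx),
        )

    def zero_variance_genes(self) -> np.ndarray:
        """Boolean flag per gene: True where the column is constant."""
        return np.ptp(self.values, axis=0) == 0


@dataclass(frozen=True)
class LabelVector:
    """Integer class labels in 1..n_classes for n paired observations."""

    labels: np.ndarray
    n_classes: int

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 1:
            raise ParameterError("labels must be a 1-D vector")
        if self.n_classes < 1:
            raise ParameterError("n_classes must be >= 1")
        if lab.size and (lab.min() < 1 or lab.max() > self.n_classes):
            raise ParameterError(
                f"labels must lie in 1..{self.n_classes}, got range "
                f"[{lab.min()}, {lab.max()}]"
            )

    @property
    def n(self) -> int:
        return self.labels.size

    @staticmethod
    def from_raw(raw) -> "LabelVector":
        """Relabel arbitrary hashable labels to 1..G (order of first appearance)."""
        raw = list(raw)
        seen: dict = {}
        out = np.empty(len(raw), dtype=int)
        for i, r in enumerate(raw):
            if r not in seen:
                seen[r] = len(seen) + 1
            out[i] = seen[r]
        return LabelVector(out, len(seen) if seen else 1)


@dataclass(frozen=True)
class FeatureSubset:
    """An ordered collection of gene positions (0-based), best first."""

    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        object.__setattr__(self, "indices", idx)
        if idx.ndim != 1 or idx.size < 1:
            raise ParameterError("a feature subset needs at least one index")
        if len(set(idx.tolist())) != idx.size:
            raise ParameterError("feature indices must be distinct")
        if idx.min() < 0:
            raise ParameterError("feature indices must be nonnegative")

    @property
    def k(self) -> int:
        return self.indices.size


@dataclass
class RunConfig:
    """All tunable constants of the pipeline, with reproducibility seed.

    The pruning threshold (0.95) and kernel-adequacy threshold (0.7) are the
    pipeline defaults; kernel grids default to the 55-kernel bank.
    """

    n_clusters: int = 2
    latent_dim: int = 2
    seed: int = 0
    # kernel bank grids
    kernel_k_grid: tuple = tuple(range(10, 31, 2))
    kernel_sigma_grid: tuple = (1.0, 1.25, 1.5, 1.75, 2.0)
    # single Gaussian kernel (grid midpoints)
    single_k: int = 20
    single_sigma: float = 1.5
    # selection-pipeline thresholds
    prune_nmi: float = 0.95
    adequacy_nmi: float = 0.7
    # k-grid for the subset sweep: dense integers 2..dense_k_max plus
    # n_log_grid log-spaced points up to p
    dense_k_max: int = 50
    n_log_grid: int = 40
    prune_cap: int = 500
    # embedding
    tsne_iters: int = 1000
    tsne_learning_rate: float | str = "auto"
    tsne_early_exaggeration: float = 12.0
    kmeans_restarts: int = 50
    # SIMLR
    simlr_beta: float = 1.0
    simlr_gamma: float = 1.0
    simlr_rho: float = 1.0
    simlr_max_iter: int = 30
    simlr_tol: float = 1e-6
    # kriging / scoring
    frk_rank_ladder: tuple | None = None  # None = automatic ladder
    score_correlation: str = "pearson"  # or "spearman"

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ParameterError("n_clusters must be >= 1")
        if self.latent_dim not in (1, 2, 3):
            raise ParameterError("latent_dim must be 1, 2 or 3")
        for name in ("prune_nmi", "adequacy_nmi"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ParameterError(f"{name} must lie in (0, 1)")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    # pandas silently mangles duplicate header names; check the raw header
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    if len(set(header)) != len(header):
        raise ParseError(f"duplicate column ids in {path}")
    try:
        df = pd.read_csv(
            path, sep=sep, index_col=0, keep_default_na=False, na_values=[],
            dtype=str,
        )
    except pd.errors.ParserError as e:  # ragged rows and friends
        raise ParseError(f"cannot parse {path}: {e}") from e
    return df


def read_expression(path, orientation: str | None = None,
                    genes_file=None, barcodes_file=None) -> ExpressionMatrix:
    """Read an expression matrix from CSV/TSV (header + id column) or MTX.

    Parameters
    ----------
    orientation : {"cells_by_genes", "genes_by_cells", None}
        Layout of the file on disk.  ``None`` chooses the community
        convention: cells × genes for delimited text, genes × cells for
        MatrixMarket.
    genes_file, barcodes_file : paths to the MTX sidecar name files
        (default ``genes.txt`` and ``barcodes.txt`` next to the matrix).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    is_mtx = path.suffix.lower() == ".mtx"
    if orientation is None:
        orientation = "genes_by_cells" if is_mtx else "cells_by_genes"
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ParameterError(f"unknown orientation {orientation!r}")

    if is_mtx:
        mat = scipy_io.mmread(path)
        if sparse.issparse(mat):
            mat = mat.toarray()
        mat = np.asarray(mat, dtype=float)
        genes_file = Path(genes_file) if genes_file else path.parent / "genes.txt"
        barcodes_file = (
            Path(barcodes_file) if barcodes_file else path.parent / "barcodes.txt"
        )
        genes = [ln.strip() for ln in genes_file.read_text().splitlines() if ln.strip()]
        cells = [ln.strip() for ln in barcodes_file.read_text().splitlines() if ln.strip()]
        if orientation == "genes_by_cells":
            mat = mat.T
        if mat.shape != (len(cells), len(genes)):
            raise ParseError(
                f"matrix shape {mat.shape} does not match sidecars "
                f"({len(cells)} barcodes, {len(genes)} genes)"
            )
        return ExpressionMatrix(mat, cells, genes)

    df = _read_delimited(path)
    num = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    if num.isna().any().any():
        bad = np.argwhere(num.isna().to_numpy())[0]
        raise ParseError(
            f"non-numeric entry {df.iat[bad[0], bad[1]]!r} at row "
            f"{df.index[bad[0]]!r}, column {df.columns[bad[1]]!r} in {path}"
        )
    values = num.to_numpy(dtype=float)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if orientation == "genes_by_cells":
        values = values.T
        rows, cols = cols, rows
    return ExpressionMatrix(values, rows, cols)


def write_expression(X: ExpressionMatrix, path) -> None:
    """Write cells × genes CSV/TSV (separator chosen by extension)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt", ".tab"} else ","
    df = pd.DataFrame(X.values, index=list(X.cell_ids), columns=list(X.gene_ids))
    df.to_csv(path, sep=sep)


def read_labels(path, n_classes: int | None = None) -> tuple:
    """Read a two-column TSV (cell_id, label); returns (cell_ids, LabelVector)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"],
                     dtype={"cell_id": str})
    lv = LabelVector.from_raw(df["label"].tolist())
    if n_classes is not None and lv.n_classes != n_classes:
        lv = LabelVector(lv.labels, n_classes)
    return list(df["cell_id"]), lv


def write_labels(cell_ids: Sequence[str], y: LabelVector, path) -> None:
    pd.DataFrame({"cell_id": list(cell_ids), "label": y.labels}).to_csv(
        Path(path), sep="\t", header=False, index=False
    )


def write_report(result, path) -> None:
    """Serialize a pipeline result (anything with ``to_dict``) to JSON."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"directory {path.parent} does not exist")
    payload = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
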