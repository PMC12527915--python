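"""Count-matrix I/O, normalization, binomial downsampling and gene sampling.

The sole primary input to the model is a raw cell x gene count matrix.
Expression values are normalized per cell with the shifted logarithm

    x~_{n,g} = ln(L * x_{n,g} / sum_g' x_{n,g'} + 1),

with a fixed scale factor L = 1e4 by default.  Self-supervised pretraining
thins counts binomially: each entry is replaced by a draw from
Binomial(x, 1/r) for a downsample rate r >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "shifted_log_normalize",
    "binomial_downsample",
    "sample_nonzero_genes",
]


class ValidationError(ValueError):
    """Raised when an input violates a data-contract invariant."""


@dataclass
class CountMatrix:
    """Raw integer counts, cells x genes.

    Invariants: counts are non-negative integers, gene ids are unique and
    every cell has a positive total (zero-total cells are dropped by the
    loaders before construction).
    """

    cell_ids: list[str]
    gene_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D cells x genes matrix")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.all(self.counts == np.round(self.counts)):
                raise ValidationError("counts contain non-integer entries")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise ValidationError("counts contain negative entries")
        totals = self.counts.sum(axis=1)
        if self.n_cells and totals.min() <= 0:
            bad = [self.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
            raise ValidationError(f"cells with zero total count: {bad}")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def row(self, cell: int | str) -> np.ndarray:
        if isinstance(cell, str):
            cell = self.cell_ids.index(cell)
        return self.counts[cell]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None


@dataclass
class NormalizedMatrix:
    """Shifted-log-normalized expression on the same cell/gene ids."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    scale_factor: float = 1e4

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def row(self, cell: int | str) -> np.ndarray:
        if isinstance(cell, str):
            cell = self.cell_ids.index(cell)
        return self.values[cell]


def _drop_zero_cells(
    cell_ids: list[str], counts: np.ndarray
) -> tuple[list[str], np.ndarray]:
    totals = counts.sum(axis=1)
    keep = totals > 0
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("dropping %d cells with zero total count", n_drop)
        cell_ids = [c for c, k in zip(cell_ids, keep) if k]
        counts = counts[keep]
    return cell_ids, counts


def read_count_matrix(path: str | Path, format: str = "mtx") -> CountMatrix:
    """Load a count matrix from disk.

    ``format="mtx"`` expects a MatrixMarket file plus sidecars ``cells.tsv``
    and ``genes.tsv`` (one id per line) in the same directory; the matrix is
    cells x genes.  ``format="tsv"`` expects a dense table whose header row
    holds gene ids and whose first column holds cell ids.  Cells with zero
    total count are dropped with a logged warning.
    """
    path = Path(path)
    if format == "mtx":
        try:
            mat = scipy.io.mmread(path)
        except Exception as exc:  # pragma: no cover - scipy message passthrough
            raise ValidationError(f"malformed MatrixMarket file {path}: {exc}") from exc
        counts = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat
        )
        cell_ids = path.with_name("cells.tsv").read_text().split()
        gene_ids = path.with_name("genes.tsv").read_text().split()
    elif format == "tsv":
        lines = Path(path).read_text().rstrip("\n").split("\n")
        if not lines or not lines[0]:
            raise ValidationError(f"empty file {path}")
        gene_ids = lines[0].split("\t")[1:]
        cell_ids, rows = [], []
        for ln, line in enumerate(lines[1:], start=2):
            parts = line.split("\t")
            if len(parts) != len(gene_ids) + 1:
                raise ValidationError(f"{path}:{ln}: expected {len(gene_ids) + 1} fields")
            cell_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise ValidationError(f"{path}:{ln}: {exc}") from exc
        counts = np.asarray(rows)
    else:
        raise ValueError(f"unknown format {format!r}")
    cell_ids, counts = _drop_zero_cells(cell_ids, counts)
    return CountMatrix(cell_ids, gene_ids, counts)


def write_count_matrix(x: CountMatrix, path: str | Path, format: str = "mtx") -> None:
    """Write a count matrix; inverse of :func:`read_count_matrix`."""
    path = Path(path)
    if format == "mtx":
        path.parent.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(x.counts))
        path.with_name("cells.tsv").write_text("\n".join(x.cell_ids) + "\n")
        path.with_name("genes.tsv").write_text("\n".join(x.gene_ids) + "\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("cell_id\t" + "\t".join(x.gene_ids) + "\n")
            for cid, row in zip(x.cell_ids, x.counts):
                fh.write(cid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def shifted_log_normalize(x: CountMatrix, L: float = 1e4) -> NormalizedMatrix:
    """Per-cell proportion scaling by ``L``, then ln(. + 1).

    Natural log; maps raw zeros to exactly zero and is strictly increasing
    in the count for a fixed cell total.
    """
    if L <= 0:
        raise ValueError("scale factor L must be positive")
    totals = x.counts.sum(axis=1, keepdims=True)
    if x.n_cells and totals.min() <= 0:
        raise ValidationError("zero-total cell; should have been dropped at load")
    values = np.log1p(L * x.counts / totals)
    return NormalizedMatrix(x.cell_ids, x.gene_ids, values, scale_factor=L)


def normalize_rows(counts: np.ndarray, L: float = 1e4) -> np.ndarray:
    """Shifted-log normalization on a bare array (rows = cells)."""
    counts = np.atleast_2d(counts)
    totals = counts.sum(axis=1, keepdims=True)
    if totals.min() <= 0:
        raise ValidationError("zero-total cell")
    return np.log1p(L * counts / totals)


def binomial_downsample(
    x: CountMatrix, rate: float, seed: int | np.random.Generator
) -> CountMatrix:
    """Thin every count with Binomial(x, 1/rate); rate >= 1.

    ``rate == 1`` returns the input counts unchanged (bitwise) for any seed.
    """
    if rate < 1:
        raise ValueError(f"downsample rate must be >= 1, got {rate}")
    if rate == 1:
        return CountMatrix(list(x.cell_ids), list(x.gene_ids), x.counts.copy())
    rng = np.random.default_rng(seed)
    ds = rng.binomial(x.counts, 1.0 / rate)
    # thinning may empty a cell; keep the construction valid by retaining
    # one count of the cell's most expressed gene (rare at desk scale)
    totals = ds.sum(axis=1)
    empty = np.flatnonzero(totals == 0)
    if empty.size:
        ds[empty, np.argmax(x.counts[empty], axis=1)] = 1
    return CountMatrix(list(x.cell_ids), list(x.gene_ids), ds)


def downsample_row(
    row: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Single-row binomial thinning used inside training loops."""
    if rate < 1:
        raise ValueError(f"downsample rate must be >= 1, got {rate}")
    if rate == 1:
        return row.copy()
    ds = rng.binomial(row, 1.0 / rate)
    if ds.sum() == 0:
        ds[int(np.argmax(row))] = 1
    return ds


def sample_nonzero_genes(
    cell: np.ndarray,
    max_genes: int = 2048,
    seed: int | np.random.Generator | None = None,
    training: bool = False,
) -> np.ndarray:
    """Gene indices fed to the encoder for one cell.

    Only genes with non-zero counts are used.  During training a uniform
    random subset of at most ``max_genes`` is drawn (without replacement);
    at inference all non-zero genes are kept.  The result is sorted by gene
    index — downstream attention is permutation-invariant, sorting just
    makes batches deterministic.
    """
    cell = np.asarray(cell)
    nonzero = np.flatnonzero(cell)
    if nonzero.size == 0:
        raise ValidationError("all-zero cell")
    if not training or nonzero.size <= max_genes:
        return nonzero
    rng = np.random.default_rng(seed)
    chosen = rng.choice(nonzero, size=max_genes, replace=False)
    return np.sort(chosen)
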