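"""Expression-matrix preprocessing: log-normalization, min-max scaling and
highly-variable-gene (HVG) selection.

Cells are rows, genes are columns. Log-normalization follows the dominant
single-cell convention: scale each cell to a fixed total (default 10 000
counts) and apply ``log1p``. HVGs are ranked by dispersion
(variance / mean) measured on the normalized count scale (the Seurat
convention: the log is undone before taking moments), with ties broken
towards the lower gene index so selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ExpressionMatrix", "log_normalize", "minmax_scale", "select_hvg"]

DEFAULT_TARGET_SUM = 10_000.0


@dataclass
class ExpressionMatrix:
    """A dense cells × genes matrix with identifiers.

    ``transforms`` records the normalization steps already applied, in order
    (e.g. ``["log_normalize", "minmax_scale"]``).
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    transforms: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (cells × genes)")
        n, d = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != d:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {d} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell ids must be unique")
        if len(set(self.gene_ids)) != d:
            raise ValueError("gene ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains NaN or Inf")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, index: np.ndarray) -> "ExpressionMatrix":
        index = np.asarray(index, dtype=np.intp)
        return replace(
            self,
            values=self.values[:, index].copy(),
            gene_ids=[self.gene_ids[i] for i in index],
            transforms=list(self.transforms),
        )


def log_normalize(counts: ExpressionMatrix,
                  target_sum: float = DEFAULT_TARGET_SUM) -> ExpressionMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply log1p.

    Zero entries stay zero, so the sparsity pattern is preserved. A cell
    with zero total counts cannot be normalized and raises ``ValueError``
    naming the offending cell.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    if np.any(counts.values < 0):
        raise ValueError("counts must be non-negative")
    totals = counts.values.sum(axis=1)
    dead = np.flatnonzero(totals == 0)
    if dead.size:
        raise ValueError(
            f"cell '{counts.cell_ids[dead[0]]}' (row {dead[0]}) has zero total counts"
        )
    scaled = counts.values * (target_sum / totals)[:, None]
    return replace(counts, values=np.log1p(scaled),
                   transforms=counts.transforms + ["log_normalize"])


def minmax_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every gene column to [0, 1]; constant columns map to zeros."""
    lo = matrix.values.min(axis=0)
    hi = matrix.values.max(axis=0)
    span = hi - lo
    constant = span == 0
    span = np.where(constant, 1.0, span)
    scaled = (matrix.values - lo) / span
    scaled[:, constant] = 0.0
    return replace(matrix, values=scaled,
                   transforms=matrix.transforms + ["minmax_scale"])


def gene_dispersion(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene dispersion = variance / mean; zero-mean genes get 0.

    Follows the classic Seurat-style convention: when the matrix is
    log-normalized, the log is undone (expm1) before taking moments, so
    dispersion is measured on the normalized count scale. On the log scale
    the statistic is dominated by lowly expressed, noisy genes rather than
    genes with real between-cell structure.
    """
    x = matrix.values
    if "log_normalize" in matrix.transforms and "minmax_scale" not in matrix.transforms:
        x = np.expm1(x)
    mean = x.mean(axis=0)
    var = x.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    return disp


def select_hvg(matrix: ExpressionMatrix, n_top: int) -> np.ndarray:
    """Indices of the ``n_top`` most dispersed genes, descending dispersion.

    Ties break towards the lower gene index; the result is fully
    deterministic and invariant to cell order.
    """
    if n_top <= 0:
        raise ValueError("n_top must be positive")
    if n_top > matrix.n_genes:
        raise ValueError(
            f"n_top={n_top} exceeds the number of genes ({matrix.n_genes})")
    disp = gene_dispersion(matrix)
    # stable sort on (-dispersion, index): equal dispersions keep index order
    order = np.argsort(-disp, kind="stable")
    return order[:n_top]
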