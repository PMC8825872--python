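"""Readers and writers for expression matrices, graphs and run artifacts.

Supported dialects: 10x-style Matrix Market (``matrix.mtx`` with
``barcodes.tsv``/``features.tsv`` side files; genes are MTX rows, cells
are columns) and dense CSV/TSV with cells as rows and a header row of
gene identifiers.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .preprocess import ExpressionMatrix

__all__ = ["read_expression", "write_expression", "read_expression_mtx",
           "read_expression_csv", "write_expression_mtx", "write_embedding_csv",
           "write_labels_csv", "write_attention_tsv", "write_gene_report_tsv"]


def read_expression(path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix, inferring the format from the path.

    ``path`` is either a directory / ``.mtx`` file (Matrix Market triple)
    or a ``.csv``/``.tsv`` file (cells in rows, gene-id header).
    """
    path = Path(path)
    if format is None:
        if path.is_dir() or path.suffix == ".mtx":
            format = "mtx"
        elif path.suffix in (".csv", ".tsv"):
            format = "csv"
        else:
            raise ValueError(f"cannot infer format of '{path}'")
    if format == "mtx":
        return read_expression_mtx(path)
    if format == "csv":
        return read_expression_csv(path)
    raise ValueError(f"unknown format '{format}'")


def read_expression_mtx(path) -> ExpressionMatrix:
    """Read a 10x-style triple: matrix.mtx + barcodes.tsv + features.tsv."""
    path = Path(path)
    if path.is_dir():
        mtx, barcodes, features = (path / "matrix.mtx", path / "barcodes.tsv",
                                   path / "features.tsv")
    else:
        mtx = path
        barcodes = path.with_name("barcodes.tsv")
        features = path.with_name("features.tsv")
    for f in (mtx, barcodes, features):
        if not f.exists():
            raise FileNotFoundError(f"missing {f}")
    m = spio.mmread(mtx)  # genes × cells, 10x convention
    values = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=np.float64).T
    cell_ids = [l.split("\t")[0] for l in barcodes.read_text().splitlines() if l]
    gene_ids = [l.split("\t")[0] for l in features.read_text().splitlines() if l]
    if len(cell_ids) != values.shape[0]:
        raise ValueError(
            f"{barcodes}: {len(cell_ids)} barcodes for {values.shape[0]} cells")
    if len(gene_ids) != values.shape[1]:
        raise ValueError(
            f"{features}: {len(gene_ids)} features for {values.shape[1]} genes")
    return ExpressionMatrix(values=values, cell_ids=cell_ids, gene_ids=gene_ids)


def read_expression_csv(path) -> ExpressionMatrix:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    return ExpressionMatrix(values=df.to_numpy(dtype=np.float64),
                            cell_ids=[str(c) for c in df.index],
                            gene_ids=[str(g) for g in df.columns])


def write_expression(matrix: ExpressionMatrix, path,
                     header_comment: str | None = None) -> None:
    """Write as CSV (cells in rows) or MTX triple, by extension/directory."""
    path = Path(path)
    if path.suffix in (".csv", ".tsv"):
        sep = "\t" if path.suffix == ".tsv" else ","
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            pd.DataFrame(matrix.values, index=matrix.cell_ids,
                         columns=matrix.gene_ids).to_csv(fh, sep=sep)
    else:
        write_expression_mtx(matrix, path)


def write_expression_mtx(matrix: ExpressionMatrix, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(outdir / "matrix.mtx"),
                 sparse.csr_matrix(matrix.values.T))  # genes × cells
    (outdir / "barcodes.tsv").write_text("\n".join(matrix.cell_ids) + "\n")
    (outdir / "features.tsv").write_text("\n".join(matrix.gene_ids) + "\n")


def write_embedding_csv(embedding: np.ndarray, cell_ids, path,
                        header_comment: str | None = None) -> None:
    emb = np.asarray(embedding)
    cols = [f"latent_{i}" for i in range(emb.shape[1])]
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame(emb, index=cell_ids, columns=cols).to_csv(fh)


def write_labels_csv(labels, cell_ids, path,
                     header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        pd.DataFrame({"label": np.asarray(labels, dtype=int)},
                     index=cell_ids).to_csv(fh)


def write_attention_tsv(records, path, header_comment: str | None = None) -> None:
    """Export attention as TSV: layer, head, target, source, alpha."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("layer\thead\ttarget\tsource\talpha\n")
        for rec in records:
            for layer, head, t, s, a in rec.to_rows():
                fh.write(f"{layer}\t{head}\t{t}\t{s}\t{a:.8g}\n")


def write_gene_report_tsv(report, gene_ids, products, path,
                          header_comment: str | None = None) -> None:
    """Export the marker report: cluster, rank, gene, appearances, max |P_mu|."""
    pmax = np.abs(products.P_mu).max(axis=1)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("cluster\trank\tgene_id\tappearance_count\tmax_weight\n")
        for cluster, genes in report.appearance.items():
            for rank, (g, count) in enumerate(genes):
                fh.write(f"{cluster}\t{rank}\t{gene_ids[g]}\t{count}\t{pmax[g]:.8g}\n")
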