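"""Matrix containers and readers/writers for copy-number and expression data.

Dense CSV/TSV matrices are read as cells x features with a header row of
feature identifiers and the first column holding cell identifiers.
Sparse expression data is read from a MatrixMarket triplet
(``matrix.mtx`` + ``barcodes.tsv`` + ``genes.tsv``/``features.tsv``);
the common genes x cells orientation is auto-detected and transposed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class MatrixFormatError(ValueError):
    """Raised when an input matrix file is malformed or inconsistent."""


@dataclass
class CNMatrix:
    """Raw cells x genomic-bins copy-number matrix.

    Copy numbers are non-negative reals (integer states in practice, but
    callers may emit fractional estimates).
    """

    values: np.ndarray
    cell_ids: list[str]
    bin_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("copy-number matrix must be 2-dimensional")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise MatrixFormatError("copy-number matrix must be non-empty")
        if len(self.cell_ids) != n:
            raise MatrixFormatError(
                f"{len(self.cell_ids)} cell ids for {n} rows"
            )
        if len(self.bin_ids) != m:
            raise MatrixFormatError(f"{len(self.bin_ids)} bin ids for {m} columns")
        if len(set(self.cell_ids)) != n:
            raise MatrixFormatError("cell ids must be unique")
        if np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise MatrixFormatError(
                f"negative copy number at cell {self.cell_ids[i]!r}, "
                f"bin {self.bin_ids[j]!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ExprMatrix:
    """Raw cells x genes UMI count matrix."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise MatrixFormatError("expression matrix must be 2-dimensional")
        n, g = self.counts.shape
        if len(self.cell_ids) != n:
            raise MatrixFormatError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(self.gene_ids) != g:
            raise MatrixFormatError(f"{len(self.gene_ids)} gene ids for {g} columns")
        if np.any(self.counts < 0):
            raise MatrixFormatError("UMI counts must be non-negative")
        if not np.allclose(self.counts, np.round(self.counts)):
            raise MatrixFormatError("UMI counts must be whole numbers")
        self.counts = np.asarray(np.round(self.counts), dtype=np.int64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass
class ProcessedMatrix:
    """Cells x features matrix after preprocessing, with provenance.

    ``provenance[j]`` lists the original column identifiers that feature j
    traces back to (several after adjacent-duplicate merging).
    ``transform_log`` is an ordered record of the applied steps; re-running
    the same steps on the same input reproduces ``values`` bit-identically
    because every step is deterministic and seed-free.
    """

    values: np.ndarray
    cell_ids: list[str]
    feature_ids: list[str]
    provenance: list[list[str]] = field(default_factory=list)
    transform_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.provenance:
            self.provenance = [[f] for f in self.feature_ids]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_step(
        self,
        values: np.ndarray,
        feature_ids: list[str],
        provenance: list[list[str]],
        step: dict,
    ) -> "ProcessedMatrix":
        return ProcessedMatrix(
            values=values,
            cell_ids=list(self.cell_ids),
            feature_ids=feature_ids,
            provenance=provenance,
            transform_log=self.transform_log + [step],
        )


def _read_dense(path: Path, sep: str) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: no feature columns found")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric entry ({exc})") from exc
    return values, [str(c) for c in df.index], [str(c) for c in df.columns]


def _read_id_column(path: Path) -> list[str]:
    # 10x-style sidecars are tab-separated with the id in the first column
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                out.append(line.split("\t")[0])
    return out


def read_mtx_triplet(
    mtx_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
) -> ExprMatrix:
    """Read a MatrixMarket expression triplet as cells x genes.

    Orientation is auto-detected: if the matrix is genes x cells (rows match
    the feature sidecar and columns match the barcode sidecar) it is
    transposed.
    """
    mtx_path, barcodes_path, features_path = map(
        Path, (mtx_path, barcodes_path, features_path)
    )
    for p in (mtx_path, barcodes_path, features_path):
        if not p.exists():
            raise MatrixFormatError(f"missing MTX triplet file: {p}")
    mat = scipy.io.mmread(mtx_path)
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    barcodes = _read_id_column(barcodes_path)
    genes = _read_id_column(features_path)
    nr, nc = mat.shape
    if nr == len(barcodes) and nc == len(genes):
        pass  # already cells x genes
    elif nr == len(genes) and nc == len(barcodes):
        mat = mat.T
    else:
        raise MatrixFormatError(
            f"MTX shape {nr}x{nc} matches neither {len(barcodes)} barcodes x "
            f"{len(genes)} genes nor its transpose"
        )
    return ExprMatrix(counts=mat, cell_ids=barcodes, gene_ids=genes)


def read_cn_matrix(path: str | Path) -> CNMatrix:
    """Read a dense CSV/TSV copy-number matrix (cells as rows)."""
    path = Path(path)
    if not path.exists():
        raise MatrixFormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    values, cells, bins = _read_dense(path, sep)
    return CNMatrix(values=values, cell_ids=cells, bin_ids=bins)


def read_expr_matrix(path: str | Path) -> ExprMatrix:
    """Read an expression matrix from dense CSV/TSV or an MTX triplet.

    For MTX, ``path`` is the ``.mtx`` file and ``barcodes.tsv`` plus
    ``genes.tsv`` (or ``features.tsv``) are expected alongside it.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        folder = path.parent
        features = folder / "genes.tsv"
        if not features.exists():
            features = folder / "features.tsv"
        return read_mtx_triplet(path, folder / "barcodes.tsv", features)
    if not path.exists():
        raise MatrixFormatError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    values, cells, genes = _read_dense(path, sep)
    return ExprMatrix(counts=values, cell_ids=cells, gene_ids=genes)


def write_matrix_tsv(
    path: str | Path,
    values: np.ndarray,
    row_ids: list[str],
    col_ids: list[str],
) -> None:
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    df.to_csv(path, sep="\t")


def write_expr_mtx(folder: str | Path, expr: ExprMatrix) -> None:
    """Write an expression matrix as a genes x cells MTX triplet."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.csr_matrix(expr.counts.T)
    scipy.io.mmwrite(str(folder / "matrix.mtx"), sparse, field="integer")
    (folder / "barcodes.tsv").write_text("\n".join(expr.cell_ids) + "\n")
    (folder / "genes.tsv").write_text(
        "\n".join(f"{g}\t{g}" for g in expr.gene_ids) + "\n"
    )


def write_processed(path: str | Path, m: ProcessedMatrix) -> None:
    """Write a processed matrix as TSV with a JSON provenance sidecar."""
    path = Path(path)
    write_matrix_tsv(path, m.values, m.cell_ids, m.feature_ids)
    sidecar = path.with_suffix(path.suffix + ".provenance.json")
    sidecar.write_text(
        json.dumps(
            {
                "feature_ids": m.feature_ids,
                "provenance": m.provenance,
                "transform_log": m.transform_log,
            },
            indent=1,
        )
    )


def drop_zero_total_cells(expr: ExprMatrix, strict: bool = False) -> ExprMatrix:
    """Drop cells whose total UMI count is zero (warn), or raise if strict."""
    totals = expr.counts.sum(axis=1)
    keep = totals > 0
    if keep.all():
        return expr
    bad = [expr.cell_ids[i] for i in np.flatnonzero(~keep)]
    if strict:
        raise MatrixFormatError(f"cells with zero total UMI count: {bad}")
    warnings.warn(
        f"dropping {len(bad)} cell(s) with zero total UMI count: {bad[:5]}",
        stacklevel=2,
    )
    return ExprMatrix(
        counts=expr.counts[keep],
        cell_ids=[c for c, k in zip(expr.cell_ids, keep) if k],
        gene_ids=list(expr.gene_ids),
    )
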