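"""Preprocessing of copy-number and expression matrices.

Copy-number branch: log2 transform (non-finite results zeroed), merge of
adjacent identical columns, removal of constant columns, then selection of
the 1024 columns with the largest coefficient of variation.  The expression
branch depth-normalizes UMI counts to the median library size, adds a
pseudocount and log2-transforms, then applies the same dimensionality
reduction.  All steps are deterministic and seed-free.
"""

from __future__ import annotations

import numpy as np

from .io import CNMatrix, ExprMatrix, MatrixFormatError, ProcessedMatrix, drop_zero_total_cells

DEFAULT_N_FEATURES = 1024


def _as_processed(cn: CNMatrix) -> ProcessedMatrix:
    return ProcessedMatrix(
        values=cn.values.copy(),
        cell_ids=list(cn.cell_ids),
        feature_ids=list(cn.bin_ids),
    )


def log2_transform_cn(cn: CNMatrix) -> ProcessedMatrix:
    """log2-transform copy numbers; non-finite results (log2 of 0) become 0.

    Negative entries are rejected by the :class:`CNMatrix` invariant, so the
    only non-finite results are -inf (zero copies), which are zeroed along
    with any NaN.
    """
    m = _as_processed(cn)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.log2(m.values)
    vals[~np.isfinite(vals)] = 0.0
    return m.with_step(
        vals, m.feature_ids, m.provenance, {"step": "log2_transform_cn"}
    )


def merge_adjacent_identical_columns(m: ProcessedMatrix) -> ProcessedMatrix:
    """Collapse maximal runs of consecutive identical columns to one column.

    Column order is otherwise preserved; provenance records every original
    column merged into each survivor.
    """
    vals = m.values
    if vals.shape[1] == 0:
        raise MatrixFormatError("matrix has no columns")
    # True at j where column j starts a new run
    if vals.shape[1] == 1:
        starts = np.array([True])
    else:
        same_as_prev = np.all(vals[:, 1:] == vals[:, :-1], axis=0)
        starts = np.concatenate([[True], ~same_as_prev])
    keep_idx = np.flatnonzero(starts)
    run_end = np.append(keep_idx[1:], vals.shape[1])
    new_vals = vals[:, keep_idx]
    feature_ids = [m.feature_ids[j] for j in keep_idx]
    provenance = [
        sum((m.provenance[k] for k in range(j, e)), [])
        for j, e in zip(keep_idx, run_end)
    ]
    return m.with_step(
        new_vals,
        feature_ids,
        provenance,
        {"step": "merge_adjacent_identical_columns", "n_merged_runs": int(
            np.sum(run_end - keep_idx > 1))},
    )


def drop_constant_columns(m: ProcessedMatrix) -> ProcessedMatrix:
    """Remove columns whose entries are identical across all cells."""
    vals = m.values
    if vals.shape[1] == 0:
        raise MatrixFormatError("matrix has no columns")
    varying = np.any(vals != vals[0, :], axis=0)
    if not varying.any():
        raise MatrixFormatError("no informative features remain")
    keep_idx = np.flatnonzero(varying)
    return m.with_step(
        vals[:, keep_idx],
        [m.feature_ids[j] for j in keep_idx],
        [m.provenance[j] for j in keep_idx],
        {"step": "drop_constant_columns",
         "n_dropped": int(vals.shape[1] - keep_idx.size)},
    )


def column_cv(vals: np.ndarray) -> np.ndarray:
    """Per-column coefficient of variation: sample sd / mean.

    Columns with non-positive mean, or with undefined sd (a single row),
    rank lowest (-inf): the CV criterion is undefined there and such
    columns carry the least usable variation signal.
    """
    mean = vals.mean(axis=0)
    if vals.shape[0] < 2:
        return np.full(vals.shape[1], -np.inf)
    sd = vals.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv[~(mean > 0)] = -np.inf
    cv[~np.isfinite(cv)] = -np.inf
    return cv


def select_top_cv_features(
    m: ProcessedMatrix, k: int = DEFAULT_N_FEATURES
) -> ProcessedMatrix:
    """Keep the k columns with the largest coefficient of variation.

    Survivors keep their original column order (genomic adjacency is
    meaningful); ties are broken by original column index, ascending.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    vals = m.values
    if vals.shape[1] <= k:
        return m.with_step(
            vals, m.feature_ids, m.provenance,
            {"step": "select_top_cv_features", "k": k, "selected": vals.shape[1]},
        )
    cv = column_cv(vals)
    # stable sort on -cv: equal CVs keep ascending original index
    order = np.argsort(-cv, kind="stable")[:k]
    keep_idx = np.sort(order)
    return m.with_step(
        vals[:, keep_idx],
        [m.feature_ids[j] for j in keep_idx],
        [m.provenance[j] for j in keep_idx],
        {"step": "select_top_cv_features", "k": k, "selected": int(k)},
    )


def normalize_expression(e: ExprMatrix, strict: bool = False) -> ProcessedMatrix:
    """Median-library-size normalization followed by log2(x + 1).

    Entry c_ij maps to log2((c_ij / T_i) * median(T) + 1) where T_i is the
    total UMI count of cell i. Cells with T_i = 0 are dropped with a warning
    (or rejected when strict).
    """
    e = drop_zero_total_cells(e, strict=strict)
    counts = e.counts.astype(float)
    totals = counts.sum(axis=1)
    med = float(np.median(totals))
    vals = np.log2(counts / totals[:, None] * med + 1.0)
    out = ProcessedMatrix(
        values=vals,
        cell_ids=list(e.cell_ids),
        feature_ids=list(e.gene_ids),
    )
    out.transform_log.append(
        {"step": "normalize_expression", "median_total": med}
    )
    return out


def preprocess_cn_pipeline(
    cn: CNMatrix, k: int = DEFAULT_N_FEATURES
) -> ProcessedMatrix:
    """Full copy-number branch: log2, merge, drop constants, top-CV."""
    m = log2_transform_cn(cn)
    m = merge_adjacent_identical_columns(m)
    m = drop_constant_columns(m)
    return select_top_cv_features(m, k)


def preprocess_expression_pipeline(
    e: ExprMatrix,
    k: int = DEFAULT_N_FEATURES,
    order: str = "normalize-first",
    strict: bool = False,
) -> ProcessedMatrix:
    """Full expression branch.

    ``order='normalize-first'`` (default) depth-normalizes before the
    dimensionality reduction so that the CV ranking reflects biological
    variation rather than sequencing depth; ``'reduce-first'`` applies the
    reduction to raw counts and normalizes afterwards.
    """
    if order == "normalize-first":
        m = normalize_expression(e, strict=strict)
        m = merge_adjacent_identical_columns(m)
        m = drop_constant_columns(m)
        return select_top_cv_features(m, k)
    if order == "reduce-first":
        e = drop_zero_total_cells(e, strict=strict)
        m = ProcessedMatrix(
            values=e.counts.astype(float),
            cell_ids=list(e.cell_ids),
            feature_ids=list(e.gene_ids),
        )
        m = merge_adjacent_identical_columns(m)
        m = drop_constant_columns(m)
        m = select_top_cv_features(m, k)
        reduced = ExprMatrix(
            counts=m.values, cell_ids=m.cell_ids, gene_ids=m.feature_ids
        )
        norm = normalize_expression(reduced, strict=strict)
        norm.provenance = m.provenance
        norm.transform_log = m.transform_log + norm.transform_log
        return norm
    raise ValueError(f"unknown order {order!r}")
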