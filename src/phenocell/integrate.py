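"""Bulk/single-cell integration: shared genes and the correlation design matrix.

Each bulk sample is correlated (Pearson, across the shared genes) with
every cell, yielding the n x N design matrix whose columns are reordered
so cells of the same group are contiguous — the layout the group-penalized
regression expects.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import CellPartition, CorrelationMatrix, GeneMatrix
from .errors import SharedGeneError, ValidationError

log = logging.getLogger("phenocell")


def shared_genes(bulk: GeneMatrix, sc: GeneMatrix) -> list:
    """Genes present in both matrices, in the single-cell matrix's order."""
    bulk_set = set(bulk.gene_ids)
    shared = [g for g in sc.gene_ids if g in bulk_set]
    if len(shared) < 3:
        raise SharedGeneError(
            f"only {len(shared)} genes shared between bulk and single-cell "
            f"matrices; at least 3 are required to correlate"
        )
    return shared


def _standardize_rows(mat):
    """Center rows and scale by their norm; zero-variance rows become 0."""
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    norms[zero] = 1.0
    return centered / norms, zero


def correlation_matrix(bulk: GeneMatrix, sc: GeneMatrix, genes: list,
                       partition: CellPartition) -> CorrelationMatrix:
    """Pearson correlation of every bulk sample with every cell.

    Entry (i, j) is the correlation across ``genes`` between sample i's
    log2 expression and cell j's log-normalized expression. Columns are
    permuted so each group occupies a contiguous slice, keeping the
    original within-group cell order; the permutation is recorded so the
    original order is recoverable. Zero-variance vectors yield 0 entries
    with a logged warning rather than NaN.
    """
    bulk.require_stage("log_transformed")
    sc.require_stage("normalized")
    if len(genes) < 3:
        raise SharedGeneError("need at least 3 shared genes")
    bindex = {g: i for i, g in enumerate(bulk.gene_ids)}
    sindex = {g: i for i, g in enumerate(sc.gene_ids)}
    missing = [g for g in genes if g not in bindex or g not in sindex]
    if missing:
        raise ValidationError(f"genes not present in both matrices: {missing[:5]}")
    B = bulk.dense()[[bindex[g] for g in genes]]  # genes x samples
    S = sc.dense()[[sindex[g] for g in genes]]  # genes x cells
    if len(partition.cell_ids) != sc.n_columns:
        raise ValidationError("partition does not cover the single-cell matrix")

    Bz, bzero = _standardize_rows(B.T)
    Sz, szero = _standardize_rows(S.T)
    if bzero.any():
        log.warning("%d bulk samples have zero variance over shared genes",
                    int(bzero.sum()))
    if szero.any():
        log.warning("%d cells have zero variance over shared genes",
                    int(szero.sum()))
    X = Bz @ Sz.T
    X[bzero, :] = 0.0
    X[:, szero] = 0.0
    np.clip(X, -1.0, 1.0, out=X)

    order = np.argsort(partition.labels, kind="stable")
    return CorrelationMatrix(
        sample_ids=list(bulk.column_ids),
        cell_ids=[sc.column_ids[i] for i in order],
        values=X[:, order],
        group_labels=partition.labels[order],
        cell_order=order,
        shared_genes=list(genes),
    )
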