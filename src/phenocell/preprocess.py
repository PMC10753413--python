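"""Bulk and single-cell preprocessing up to the PCA embedding.

The pipeline order is fixed and enforced through stage tags:

* bulk:        average duplicates -> log2(x + 1)
* single cell: average duplicates -> gene filter -> log-normalize
               -> highly variable genes -> scale -> PCA

Normalization follows the convention common to single-cell toolkits:
counts are scaled to a fixed library size (1e4 by default) and
natural-log transformed with a pseudocount of one. Highly variable genes
are ranked by standardized variance under a variance-stabilizing
mean-variance fit on raw counts.
"""

from __future__ import annotations

import logging

import numpy as np
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from .containers import GeneMatrix, PCAEmbedding
from .errors import ValidationError

log = logging.getLogger("phenocell")


def average_duplicate_genes(m: GeneMatrix) -> GeneMatrix:
    """Collapse rows sharing a gene ID to their arithmetic mean.

    Output row order is the first-occurrence order of each gene ID;
    columns are untouched. A matrix without duplicates passes through
    with values unchanged.
    """
    ids = m.gene_ids
    first_index = {}
    for i, g in enumerate(ids):
        first_index.setdefault(g, i)
    unique = sorted(first_index, key=first_index.get)
    if len(unique) == len(ids):
        return m.copy_with()
    dense = m.dense()
    out = np.empty((len(unique), m.n_columns), dtype=float)
    pos = {g: i for i, g in enumerate(unique)}
    counts = np.zeros(len(unique))
    out[:] = 0.0
    for i, g in enumerate(ids):
        j = pos[g]
        out[j] += dense[i]
        counts[j] += 1
    out /= counts[:, None]
    return GeneMatrix(unique, m.column_ids, out, stage=m.stage)


def log2_transform_bulk(m: GeneMatrix) -> GeneMatrix:
    """log2(v + 1) on bulk counts; stage becomes log_transformed."""
    m.require_stage("raw_counts")
    vals = m.dense()
    if np.any(vals < 0):
        raise ValidationError("negative value in bulk count matrix")
    return GeneMatrix(m.gene_ids, m.column_ids, np.log2(vals + 1.0),
                      stage="log_transformed")


def filter_genes_by_cell_count(sc: GeneMatrix, min_cells: int) -> GeneMatrix:
    """Retain genes with a nonzero count in at least ``min_cells`` cells."""
    sc.require_stage("raw_counts")
    if min_cells < 0:
        raise ValidationError("min_cells must be non-negative")
    if sp.issparse(sc.values):
        ncells = np.asarray((sc.values > 0).sum(axis=1)).ravel()
    else:
        ncells = np.count_nonzero(np.asarray(sc.values) > 0, axis=1)
    keep = np.flatnonzero(ncells >= min_cells)
    genes = [sc.gene_ids[i] for i in keep]
    vals = sc.values[keep] if not sp.issparse(sc.values) else sc.values[keep, :]
    return GeneMatrix(genes, sc.column_ids, vals, stage="raw_counts")


def lognormalize_sc(sc: GeneMatrix, scale_factor: float = 1e4) -> GeneMatrix:
    """Library-size normalize and natural-log transform single-cell counts.

    A count c in a cell with total T becomes ln(1 + c * scale_factor / T),
    which is invariant to rescaling all of a cell's counts by a constant.
    """
    sc.require_stage("raw_counts")
    dense = sc.dense()
    totals = dense.sum(axis=0)
    if np.any(totals <= 0):
        raise ValidationError("cell with zero total counts cannot be normalized")
    out = np.log1p(dense * (scale_factor / totals)[None, :])
    return GeneMatrix(sc.gene_ids, sc.column_ids, out, stage="normalized")


def _mean_variance_trend(lx, ly, span):
    """Robust local-regression trend of log10(var) on log10(mean).

    High-dispersion genes are exactly what the trend must not chase, and
    at the edges of the mean range they have enough leverage to drag a
    plain local fit through themselves. A global Theil-Sen line (no
    boundary leverage) flags >3-MAD outliers first; the lowess curve
    (span ``span``) is then fit on the remaining genes and interpolated
    back to every gene.
    """
    from scipy import stats

    if lx.shape[0] < 4 or np.ptp(lx) < 1e-12:
        return np.full(lx.shape[0], np.median(ly))
    if lx.shape[0] > 2000:  # Theil-Sen is O(n^2); thin deterministically
        idx = np.linspace(0, lx.shape[0] - 1, 2000).astype(int)
        order = np.argsort(lx)
        sub = order[idx]
        slope, intercept, *_ = stats.theilslopes(ly[sub], lx[sub])
    else:
        slope, intercept, *_ = stats.theilslopes(ly, lx)
    resid = ly - (intercept + slope * lx)
    med = np.median(resid)
    mad = np.median(np.abs(resid - med)) * 1.4826
    keep = np.abs(resid - med) <= 3.0 * max(mad, 1e-12)
    if keep.sum() < max(5, lx.shape[0] // 2):
        keep = np.ones(lx.shape[0], dtype=bool)
    xs, ys = lx[keep], ly[keep]
    o = np.argsort(xs)
    fitted_kept = lowess(ys, xs, frac=span, it=3, return_sorted=False)
    return np.interp(lx, xs[o], fitted_kept[o])


def _vst_standardized_variance(counts: np.ndarray, span: float = 0.3):
    """Standardized variance per gene under the variance-stabilizing fit.

    Fits the mean-variance trend on log10 scale over genes with positive
    variance, standardizes counts by the fitted standard deviation,
    clips standardized values at sqrt(n_cells), and returns the variance
    of the clipped values.
    """
    n_cells = counts.shape[1]
    mean = counts.mean(axis=1)
    var = counts.var(axis=1, ddof=1)
    std_var = np.zeros(counts.shape[0])
    ok = (var > 0) & (mean > 0)
    if ok.sum() >= 2:
        fitted = _mean_variance_trend(np.log10(mean[ok]), np.log10(var[ok]),
                                      span)
        exp_sd = np.sqrt(10.0 ** fitted)
        clip = np.sqrt(n_cells)
        sub = counts[ok]
        z = (sub - mean[ok][:, None]) / exp_sd[:, None]
        np.clip(z, -clip, clip, out=z)
        # variance about the clipped mean, matching the vst convention
        std_var[ok] = np.square(z - z.mean(axis=1, keepdims=True)).sum(axis=1) / (
            n_cells - 1
        )
    return std_var


def select_hvg(sc: GeneMatrix, n_hvg: int = 2000) -> list:
    """Top ``n_hvg`` genes by standardized variance (raw counts).

    Ties are broken by lexicographic gene ID so the selection is
    deterministic; if ``n_hvg`` exceeds the gene count the whole list is
    returned with a warning.
    """
    counts = sc.dense()
    if n_hvg > sc.n_genes:
        log.warning(
            "n_hvg=%d exceeds gene count %d; returning all genes", n_hvg, sc.n_genes
        )
        n_hvg = sc.n_genes
    std_var = _vst_standardized_variance(counts)
    order = sorted(range(sc.n_genes), key=lambda i: (-std_var[i], sc.gene_ids[i]))
    return [sc.gene_ids[i] for i in order[:n_hvg]]


def scale_and_pca(sc: GeneMatrix, hvg: list, n_pcs: int) -> PCAEmbedding:
    """Scale HVG rows and embed cells in the top ``n_pcs`` components.

    Each gene is centered and unit-scaled across cells, scaled values are
    clipped at +10, and the cell x gene matrix is decomposed by SVD. The
    sign of each component is fixed so its largest-magnitude gene loading
    is positive, making embeddings reproducible across platforms.
    """
    sc.require_stage("normalized")
    if sc.n_columns < n_pcs:
        raise ValidationError(
            f"need at least n_pcs={n_pcs} cells, got {sc.n_columns}"
        )
    index = {g: i for i, g in enumerate(sc.gene_ids)}
    rows = [index[g] for g in hvg if g in index]
    data = sc.dense()[rows]  # genes x cells
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (data - mean) / sd
    np.clip(z, None, 10.0, out=z)
    X = z.T  # cells x genes, already gene-centered
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    n_pcs = min(n_pcs, S.shape[0])
    U, S, Vt = U[:, :n_pcs], S[:n_pcs], Vt[:n_pcs]
    # deterministic sign: largest |loading| per component is positive
    for k in range(n_pcs):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    coords = U * S
    explained = (S ** 2) / max(X.shape[0] - 1, 1)
    return PCAEmbedding(list(sc.column_ids), coords, explained)


def preprocess_bulk(bulk: GeneMatrix) -> GeneMatrix:
    """Full bulk chain: duplicate averaging then log2 transform."""
    return log2_transform_bulk(average_duplicate_genes(bulk))


def preprocess_sc(sc: GeneMatrix, min_cells: int = 400, n_hvg: int = 2000,
                  n_pcs: int = 10):
    """Full single-cell chain; returns (normalized matrix, hvg list, embedding)."""
    sc = average_duplicate_genes(sc)
    filtered = filter_genes_by_cell_count(sc, min_cells)
    normalized = lognormalize_sc(filtered)
    hvg = select_hvg(filtered, n_hvg)
    emb = scale_and_pca(normalized, hvg, n_pcs)
    return normalized, hvg, emb
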