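"""End-to-end orchestration: preprocess, group, integrate, fit, classify."""

from __future__ import annotations

import logging

import numpy as np

from .containers import PhenotypeVector
from .errors import ValidationError
from .estimators import SparseGroupLassoCV
from .grouping import build_snn_graph, leiden_partition
from .integrate import correlation_matrix, shared_genes
from .io import RunConfig
from .preprocess import preprocess_bulk, preprocess_sc
from .sgl import SGLFit
from .subpop import classify_cells

log = logging.getLogger("phenocell")


def align_phenotype(pheno: PhenotypeVector, sample_ids) -> PhenotypeVector:
    """Reorder the phenotype to the bulk sample order by ID string.

    Matching is order-independent; any unmatched ID on either side is an
    error rather than a silent drop.
    """
    index = {s: i for i, s in enumerate(pheno.sample_ids)}
    missing = [s for s in sample_ids if s not in index]
    extra = [s for s in pheno.sample_ids if s not in set(sample_ids)]
    if missing or extra:
        raise ValidationError(
            f"phenotype/bulk sample mismatch: {len(missing)} bulk samples "
            f"without phenotype (e.g. {missing[:3]}), {len(extra)} phenotype "
            f"rows without bulk sample (e.g. {extra[:3]})"
        )
    return pheno.subset([index[s] for s in sample_ids])


def fit_from_matrices(bulk_log, sc_norm, pheno, partition, config: RunConfig,
                      genes=None, annotations=None):
    """Integrate preprocessed matrices and run the cross-validated fit.

    Returns a dict with the correlation design, the selected fit (design
    order), the per-cell assignment and the CV surface.
    """
    if genes is None:
        genes = shared_genes(bulk_log, sc_norm)
    corr = correlation_matrix(bulk_log, sc_norm, genes, partition)
    if pheno.mode == "binary":
        y = pheno.y
    else:
        y = np.column_stack([pheno.time, pheno.status])
    est = SparseGroupLassoCV(
        groups=corr.group_labels,
        alpha_grid=config.alpha_grid,
        n_lambda=config.n_lambda,
        cv=config.cv_folds,
        mode=pheno.mode,
        tol=config.tol,
        max_iter=config.max_iter,
        random_state=config.random_seed,
        fix_alpha=config.fix_alpha,
        fix_lambda=config.fix_lambda,
    )
    est.fit(corr.values, y)
    fit = SGLFit(
        cell_ids=list(corr.cell_ids),
        group_labels=corr.group_labels,
        coef=est.coef_,
        intercept=est.intercept_,
        alpha=est.alpha_,
        lam=est.lambda_,
        n_iter=est.n_iter_,
        objective=est.objective_,
        kkt_residual=est.kkt_residual_,
    )
    ann = None
    if annotations is not None:
        ann = [annotations[i] for i in corr.cell_order]
    assignment = classify_cells(fit, annotations=ann)
    return dict(corr=corr, fit=fit, assignment=assignment,
                cv_result=est.cv_result_, estimator=est)


def run_pipeline(sc_raw, bulk_raw, pheno, config: RunConfig, annotations=None):
    """Full run from raw matrices to classified cells.

    Steps: bulk duplicate-averaging + log2; single-cell duplicate-
    averaging, gene filter, log-normalization, HVG selection, scaling and
    PCA; SNN graph over the first ``n_pcs`` components; Leiden grouping
    at the configured resolution; sample-cell Pearson correlation over
    shared genes; cross-validated sparse group lasso; sign
    classification.
    """
    bulk_log = preprocess_bulk(bulk_raw)
    pheno = align_phenotype(pheno, bulk_log.column_ids)
    sc_norm, hvg, emb = preprocess_sc(
        sc_raw, min_cells=config.min_cells_per_gene, n_hvg=config.n_hvg,
        n_pcs=config.n_pcs)
    graph = build_snn_graph(emb, k=config.knn_k, prune=config.snn_prune)
    partition = leiden_partition(graph, config.resolution, config.random_seed)
    log.info("Leiden: %d groups, Q=%.4f", partition.n_groups,
             partition.modularity)
    result = fit_from_matrices(bulk_log, sc_norm, pheno, partition, config,
                               annotations=annotations)
    result.update(dict(partition=partition, embedding=emb, graph=graph,
                       hvg=hvg, bulk_log=bulk_log, sc_norm=sc_norm,
                       pheno=pheno))
    return result
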