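"""Cell classification, composition summaries, differential expression and
the incomplete-data robustness protocol.

Cells are labeled by the sign of their fitted coefficient: positive
coefficients mark cells associated with the higher-encoded phenotype
(case / worse survival), negative with the lower-encoded one, and exact
zeros are background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneMatrix
from .errors import DegenerateGroupError, ValidationError

log = logging.getLogger("phenocell")

#: coefficients below this magnitude are treated as exact zeros
ZERO_THRESHOLD = 1e-12


@dataclass
class CellAssignment:
    """Per-cell label, coefficient, group id and optional annotation."""

    cell_ids: list
    labels: np.ndarray  # "positive" | "negative" | "background"
    coefficients: np.ndarray
    group_ids: np.ndarray
    annotations: list = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.group_ids = np.asarray(self.group_ids, dtype=int)


@dataclass
class DEAResult:
    """Per-gene differential expression table with its filter settings."""

    table: pd.DataFrame  # gene, log_fc, t_stat, p_value, fdr, direction, passed
    logfc_threshold: float
    sig_threshold: float
    sig_on: str

    @property
    def passing(self):
        return self.table[self.table["passed"]]


def classify_cells(fit, annotations=None, zero_threshold=ZERO_THRESHOLD):
    """Three-way sign labeling of the fitted coefficients.

    Coefficients with magnitude below ``zero_threshold`` count as exact
    zeros (background).
    """
    coef = np.asarray(fit.coef, dtype=float)
    labels = np.where(
        np.abs(coef) <= zero_threshold,
        "background",
        np.where(coef > 0, "positive", "negative"),
    )
    return CellAssignment(
        cell_ids=list(fit.cell_ids),
        labels=labels,
        coefficients=coef,
        group_ids=np.asarray(fit.group_labels, dtype=int),
        annotations=list(annotations) if annotations is not None else None,
    )


def summarize_assignment(assign: CellAssignment, by="group"):
    """Counts and within-label percentages of +/- cells per group/annotation.

    Returns a DataFrame indexed by the grouping key with columns
    ``positive_count``, ``positive_pct``, ``negative_count``,
    ``negative_pct``. A label with zero cells yields all-zero counts and
    percentages (not an error).
    """
    if by == "group":
        keys = [f"group_{g + 1}" for g in assign.group_ids]
    elif by == "annotation":
        if assign.annotations is None:
            raise ValidationError("no cell annotations available")
        keys = list(assign.annotations)
    else:
        raise ValidationError("summarize by 'group' or 'annotation'")
    df = pd.DataFrame({"key": keys, "label": assign.labels})
    uniq = sorted(set(keys))
    out = pd.DataFrame(index=uniq)
    for lab in ("positive", "negative"):
        counts = df[df["label"] == lab].groupby("key").size()
        counts = counts.reindex(uniq, fill_value=0)
        total = counts.sum()
        out[f"{lab}_count"] = counts
        out[f"{lab}_pct"] = 100.0 * counts / total if total > 0 else 0.0
    return out


def benjamini_hochberg(pvals):
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def differential_expression(expr: GeneMatrix, group_a, group_b,
                            logfc_threshold=1.0, sig_threshold=0.05,
                            sig_on="fdr") -> DEAResult:
    """Welch t-test DEA between two disjoint cell/sample sets.

    ``expr`` must be on a log scale, so the fold change is the difference
    of group means (A minus B). A gene passes when |logFC| exceeds
    ``logfc_threshold`` and its p-value (``sig_on='pvalue'``) or BH FDR
    (``sig_on='fdr'``) is below ``sig_threshold``.
    """
    if sig_on not in ("pvalue", "fdr"):
        raise ValidationError("sig_on must be 'pvalue' or 'fdr'")
    expr.require_stage("log_transformed", "normalized")
    index = {c: i for i, c in enumerate(expr.column_ids)}
    ia = np.array([index[c] for c in group_a], dtype=int)
    ib = np.array([index[c] for c in group_b], dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise DegenerateGroupError("both comparison groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValidationError("comparison groups must be disjoint")
    if ia.size < 2 or ib.size < 2:
        raise DegenerateGroupError(
            "each group needs at least 2 members for a variance estimate")
    dense = expr.dense()
    A = dense[:, ia]
    B = dense[:, ib]
    log_fc = A.mean(axis=1) - B.mean(axis=1)
    t_stat, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    # constant genes in both groups: no evidence either way
    p = np.where(np.isnan(p), 1.0, p)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    fdr = benjamini_hochberg(p)
    sig = p if sig_on == "pvalue" else fdr
    passed = (np.abs(log_fc) > logfc_threshold) & (sig < sig_threshold)
    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "log_fc": log_fc,
            "t_stat": t_stat,
            "p_value": p,
            "fdr": fdr,
            "direction": np.where(log_fc > 0, "up", "down"),
            "passed": passed,
        }
    )
    return DEAResult(table, logfc_threshold, sig_threshold, sig_on)


def robustness_protocol(bulk, sc_norm, pheno, partition, thresholds,
                        config, annotations=None, sig_threshold=0.05,
                        sig_on="pvalue"):
    """Re-run the full selection on DEG-restricted shared-gene sets.

    For each |logFC| threshold tau the two bulk phenotype classes are
    compared gene-wise (Welch t-test, raw p < ``sig_threshold``); the
    shared-gene set is cut down to the passing genes, the correlation
    matrix rebuilt and the cross-validated fit re-run. Returns a list of
    row dicts (baseline first) with the selected-cell composition; a
    threshold leaving fewer than 3 genes is recorded as degenerate.
    """
    from .pipeline import fit_from_matrices

    if pheno.mode != "binary":
        raise ValidationError("robustness protocol requires a binary phenotype")
    rows = []

    def run(genes, tau):
        result = fit_from_matrices(bulk, sc_norm, pheno, partition, config,
                                   genes=genes, annotations=annotations)
        assign = result["assignment"]
        pos = assign.labels == "positive"
        neg = assign.labels == "negative"
        comp = {}
        for g in range(partition.n_groups):
            in_g = assign.group_ids == g
            comp[f"group_{g + 1}_pos_frac"] = (
                float(np.sum(pos & in_g)) / max(1, int(pos.sum())))
        if assign.annotations is not None:
            ann = np.asarray(assign.annotations, dtype=object)
            for a in sorted(set(ann)):
                comp[f"annotation_{a}_pos_frac"] = (
                    float(np.sum(pos & (ann == a))) / max(1, int(pos.sum())))
        row = dict(threshold=tau, n_genes=len(genes),
                   n_positive=int(pos.sum()), n_negative=int(neg.sum()),
                   degenerate=False, composition=comp,
                   alpha=result["fit"].alpha, lam=result["fit"].lam,
                   coef=np.asarray(result["fit"].coef).copy())
        return row, result

    from .integrate import shared_genes as _shared

    base_genes = _shared(bulk, sc_norm)
    base_row, base_result = run(base_genes, None)
    rows.append(base_row)

    case = [s for s, y in zip(bulk.column_ids, pheno.y) if y == 1]
    ctrl = [s for s, y in zip(bulk.column_ids, pheno.y) if y == 0]
    dea = differential_expression(bulk, case, ctrl, logfc_threshold=0.0,
                                  sig_threshold=sig_threshold, sig_on=sig_on)
    tab = dea.table
    for tau in thresholds:
        keep = tab[(np.abs(tab["log_fc"]) > tau)
                   & (tab[("p_value" if sig_on == "pvalue" else "fdr")]
                      < sig_threshold)]["gene"]
        genes = [g for g in base_genes if g in set(keep)]
        if len(genes) < 3:
            rows.append(dict(threshold=tau, n_genes=len(genes),
                             n_positive=0, n_negative=0, degenerate=True,
                             composition={}, alpha=None, lam=None, coef=None))
            log.warning("threshold %.3g leaves %d genes: degenerate",
                        tau, len(genes))
            continue
        row, _ = run(genes, tau)
        rows.append(row)
    return rows, base_result
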