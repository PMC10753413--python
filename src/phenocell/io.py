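"""Reading the pipeline's input formats, run configuration and result writing.

Expression matrices arrive either as a MatrixMarket triplet (``matrix.mtx``
with ``genes.tsv``/``barcodes.tsv`` sidecars) or as a dense CSV/TSV with gene
IDs in the first column and sample/cell IDs in the header. Orientation is
fixed at the I/O boundary: rows are genes, columns are samples or cells.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from . import __version__
from .containers import GeneMatrix, PhenotypeVector
from .errors import (
    DimensionMismatchError,
    InputFileError,
    ParseError,
    ValidationError,
)

log = logging.getLogger("phenocell")

DEFAULT_ALPHA_GRID = (
    0.005, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95,
)


@dataclass
class RunConfig:
    """Configuration of a full run.

    Defaults follow the method's published operating point: Leiden
    resolution 0.6, a 12-point alpha search grid spanning (0, 1), a
    20-value lambda path chosen by 5-fold cross-validation, genes kept if
    expressed in at least 400 cells, an SNN graph over the first 10 PCs
    with k = 20 neighbors and Jaccard pruning at 1/15.
    """

    resolution: float = 0.6
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    n_lambda: int = 20
    cv_folds: int = 5
    min_cells_per_gene: int = 400
    n_hvg: int = 2000
    n_pcs: int = 10
    knn_k: int = 20
    snn_prune: float = 1.0 / 15.0
    phenotype_mode: str = "binary"
    random_seed: int = 0
    sc_path: str = ""
    bulk_path: str = ""
    phenotype_path: str = ""
    outdir: str = "phenocell_out"
    tol: float = 1e-5
    max_iter: int = 2000
    fix_alpha: float = None
    fix_lambda: float = None

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValidationError("resolution must be positive")
        self.alpha_grid = tuple(float(a) for a in self.alpha_grid)
        if not self.alpha_grid:
            raise ValidationError("alpha grid must be non-empty")
        if any(a < 0 or a > 1 for a in self.alpha_grid):
            raise ValidationError("every alpha must lie in [0, 1]")
        if list(self.alpha_grid) != sorted(self.alpha_grid):
            raise ValidationError("alpha grid must be ordered")
        if self.cv_folds < 2:
            raise ValidationError("cv_folds must be at least 2")
        if self.min_cells_per_gene < 0:
            raise ValidationError("min_cells_per_gene must be non-negative")
        if self.n_lambda < 1 or self.n_pcs < 1 or self.knn_k < 1:
            raise ValidationError("n_lambda, n_pcs and knn_k must be positive")
        if not (0 <= self.snn_prune < 1):
            raise ValidationError("snn_prune must lie in [0, 1)")
        if self.phenotype_mode not in ("binary", "survival"):
            raise ValidationError(
                "phenotype_mode must be 'binary' or 'survival' (never inferred)"
            )

    @classmethod
    def from_file(cls, path, **overrides):
        """Load a YAML or JSON config file; keyword overrides win."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config file {path} must contain a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _read_dense(path, sep):
    try:
        df = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:  # ragged rows and friends
        raise ParseError(f"malformed table in {path}: {exc}") from None
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[np.flatnonzero(bad.to_numpy())[0]]
            raise ParseError(
                f"non-numeric value at gene {row!r}, column {col!r} in {path}"
            )
        if converted.isna().any():
            row = df.index[np.flatnonzero(converted.isna().to_numpy())[0]]
            raise ParseError(f"missing value at gene {row!r}, column {col!r} in {path}")
        values[:, j] = converted.to_numpy()
    return list(df.index.astype(str)), [str(c) for c in df.columns], values


def _read_id_list(path):
    ids = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_expression(path, orientation="genes_by_columns"):
    """Read an expression matrix as genes x columns.

    ``path`` may be a dense CSV/TSV file, or a ``.mtx`` MatrixMarket file
    whose directory contains ``genes.tsv`` (or ``features.tsv``) and
    ``barcodes.tsv`` sidecars with one ID per line.
    """
    if orientation != "genes_by_columns":
        raise ValidationError("only genes_by_columns orientation is supported")
    path = Path(path)
    if not path.exists():
        raise InputFileError(f"expression file not found: {path}")
    if path.suffix == ".mtx":
        try:
            mat = scipy.io.mmread(path)
        except ValueError as exc:
            raise ParseError(f"malformed MatrixMarket file {path}: {exc}") from None
        folder = path.parent
        gene_file = folder / "genes.tsv"
        if not gene_file.exists():
            gene_file = folder / "features.tsv"
        barcode_file = folder / "barcodes.tsv"
        if not gene_file.exists() or not barcode_file.exists():
            raise InputFileError(
                f"MTX sidecars genes.tsv/features.tsv and barcodes.tsv "
                f"required next to {path}"
            )
        genes = _read_id_list(gene_file)
        barcodes = _read_id_list(barcode_file)
        mat = sp.csr_matrix(mat)
        if mat.shape != (len(genes), len(barcodes)):
            raise DimensionMismatchError(
                f"matrix {mat.shape} does not match {len(genes)} genes x "
                f"{len(barcodes)} barcodes in sidecar files"
            )
        return GeneMatrix(genes, barcodes, mat, stage="raw_counts")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    genes, cols, values = _read_dense(path, sep)
    if np.any(~np.isfinite(values)):
        raise ParseError(f"non-finite value in {path}")
    return GeneMatrix(genes, cols, values, stage="raw_counts")


def read_phenotype(path, mode):
    """Read a phenotype table keyed by sample ID.

    Binary mode expects columns ``sample_id, label`` with labels in {0,1};
    survival mode expects ``sample_id, time, status`` with positive times
    and status 1 for an observed event. The mode is always declared by the
    caller, never guessed from the column count.
    """
    path = Path(path)
    if not path.exists():
        raise InputFileError(f"phenotype file not found: {path}")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, header=0)
    if df.shape[1] < 2:
        raise ParseError(f"phenotype table {path} needs an ID column plus values")
    ids = [str(v) for v in df.iloc[:, 0]]
    if mode == "binary":
        y = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
        if np.any(~np.isfinite(y)):
            raise ParseError(f"non-numeric label in {path}")
        return PhenotypeVector(ids, "binary", y=y)
    if mode == "survival":
        if df.shape[1] < 3:
            raise ParseError(f"survival table {path} needs time and status columns")
        t = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
        s = pd.to_numeric(df.iloc[:, 2], errors="coerce").to_numpy()
        if np.any(~np.isfinite(t)) or np.any(~np.isfinite(s)):
            raise ParseError(f"non-numeric time/status in {path}")
        return PhenotypeVector(ids, "survival", time=t, status=s)
    raise ValidationError(f"unknown phenotype mode {mode!r}")


def write_expression(matrix, path):
    """Write a GeneMatrix as TSV (genes x columns); round-trips exactly."""
    df = pd.DataFrame(matrix.dense(), index=matrix.gene_ids, columns=matrix.column_ids)
    df.to_csv(path, sep="\t", float_format="%.17g")


def write_results(fit, partition, outdir, extra=None):
    """Write per-cell results (TSV) and a JSON run summary.

    The TSV has columns cell_id, group_id, coefficient, label; the JSON
    records the selected (alpha, lambda), resolution, group sizes, CV
    losses and seed. Output bytes are stable given identical inputs.
    """
    from .subpop import classify_cells

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputFileError(f"cannot create output directory {outdir}: {exc}")
    if fit.coef.shape[0] == 0:
        raise ValidationError("fit has an empty coefficient vector")
    if fit.coef.shape[0] != len(partition.cell_ids):
        raise DimensionMismatchError("fit does not cover the partition's cells")

    assign = classify_cells(fit)
    cell_tsv = outdir / "cells.tsv"
    with open(cell_tsv, "w") as fh:
        fh.write("cell_id\tgroup_id\tcoefficient\tlabel\n")
        for cid, grp, coef, lab in zip(
            fit.cell_ids, fit.group_labels, fit.coef, assign.labels
        ):
            fh.write(f"{cid}\t{int(grp) + 1}\t{coef:.10g}\t{lab}\n")

    summary = {
        "alpha": fit.alpha,
        "lambda": fit.lam,
        "resolution": partition.resolution,
        "n_groups": int(partition.n_groups),
        "group_sizes": [int(p) for p in partition.group_sizes],
        "modularity": partition.modularity,
        "n_positive": int(np.sum(assign.labels == "positive")),
        "n_negative": int(np.sum(assign.labels == "negative")),
        "n_background": int(np.sum(assign.labels == "background")),
        "version": __version__,
    }
    if extra:
        summary.update(extra)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return cell_tsv, outdir / "run_summary.json"


def setup_logging(verbose=False):
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s: %(message)s"
    )
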