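"""In-memory containers shared by the pipeline stages.

Expression matrices are held genes x columns (columns are bulk samples or
single cells) throughout the public API; stage tags enforce the fixed
preprocessing order at run time instead of by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import DimensionMismatchError, StageError, ValidationError

#: allowed preprocessing stages for a GeneMatrix
STAGES = ("raw_counts", "log_transformed", "normalized", "scaled")


@dataclass
class GeneMatrix:
    """Genes x columns expression matrix with a preprocessing stage tag.

    Parameters
    ----------
    gene_ids : list of str
        Row identifiers. Unique only after duplicate averaging.
    column_ids : list of str
        Sample or cell identifiers; always unique.
    values : ndarray or sparse matrix, shape (n_genes, n_columns)
    stage : str
        One of :data:`STAGES`.
    """

    gene_ids: list
    column_ids: list
    values: object
    stage: str = "raw_counts"

    def __post_init__(self):
        self.gene_ids = list(self.gene_ids)
        self.column_ids = list(self.column_ids)
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}")
        shape = self.values.shape
        if shape != (len(self.gene_ids), len(self.column_ids)):
            raise DimensionMismatchError(
                f"values shape {shape} does not match {len(self.gene_ids)} gene IDs "
                f"x {len(self.column_ids)} column IDs"
            )
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValidationError("column IDs must be unique")

    @property
    def n_genes(self):
        return len(self.gene_ids)

    @property
    def n_columns(self):
        return len(self.column_ids)

    def require_stage(self, *stages):
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, got {self.stage!r}"
            )

    def dense(self):
        """Values as a dense float array (copy only if sparse)."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def copy_with(self, **kw):
        args = dict(
            gene_ids=list(self.gene_ids),
            column_ids=list(self.column_ids),
            values=self.values,
            stage=self.stage,
        )
        args.update(kw)
        return GeneMatrix(**args)


@dataclass
class PCAEmbedding:
    """Cells x n_pcs coordinates with per-component explained variance."""

    cell_ids: list
    coordinates: np.ndarray
    explained_variance: np.ndarray

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        if self.coordinates.shape[0] != len(self.cell_ids):
            raise DimensionMismatchError("embedding rows != number of cell IDs")
        if self.coordinates.shape[1] != self.explained_variance.shape[0]:
            raise DimensionMismatchError("explained variance length != n_pcs")
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValidationError("explained variances must be non-increasing")

    @property
    def n_pcs(self):
        return self.coordinates.shape[1]


@dataclass
class SNNGraph:
    """Weighted undirected cell graph (shared-nearest-neighbor weights).

    ``adjacency`` is symmetric with zero diagonal; weights live in [0, 1].
    """

    cell_ids: list
    adjacency: sp.spmatrix

    def __post_init__(self):
        a = sp.csr_matrix(self.adjacency, dtype=float)
        if a.shape[0] != a.shape[1] or a.shape[0] != len(self.cell_ids):
            raise DimensionMismatchError("adjacency must be square over cell IDs")
        if abs(a - a.T).max() > 1e-12:
            raise ValidationError("adjacency must be symmetric")
        if a.diagonal().any():
            raise ValidationError("adjacency diagonal must be zero (no self-loops)")
        self.adjacency = a

    @property
    def n_cells(self):
        return self.adjacency.shape[0]

    @property
    def degrees(self):
        """Weighted degree k_i = sum_j A_ij."""
        return np.asarray(self.adjacency.sum(axis=1)).ravel()

    @property
    def total_weight(self):
        """m = half the total weighted degree."""
        return float(self.degrees.sum()) / 2.0


@dataclass
class CellPartition:
    """Assignment of cells to 1..s groups, with resolution and modularity."""

    cell_ids: list
    labels: np.ndarray  # int group index in [0, s)
    resolution: float
    modularity: float = float("nan")

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != len(self.cell_ids):
            raise DimensionMismatchError("labels length != number of cells")
        if self.labels.min(initial=0) < 0:
            raise ValidationError("group labels must be non-negative")
        # relabel to a dense 0..s-1 range preserving first-appearance order
        _, inv = np.unique(self.labels, return_inverse=True)
        order = {}
        dense = np.empty_like(self.labels)
        nxt = 0
        for i, lab in enumerate(self.labels):
            if lab not in order:
                order[lab] = nxt
                nxt += 1
            dense[i] = order[lab]
        self.labels = dense

    @property
    def n_groups(self):
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def group_sizes(self):
        """p_l for l = 1..s."""
        return np.bincount(self.labels, minlength=self.n_groups)


@dataclass
class CorrelationMatrix:
    """n samples x N cells Pearson design matrix, columns grouped contiguously.

    ``cell_order`` maps the (group-contiguous) column position back to the
    original cell index, so the original ordering is recoverable exactly.
    """

    sample_ids: list
    cell_ids: list  # in group-contiguous order
    values: np.ndarray
    group_labels: np.ndarray  # per-column group index, non-decreasing
    cell_order: np.ndarray  # original index of each column
    shared_genes: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=int)
        self.cell_order = np.asarray(self.cell_order, dtype=int)
        n, N = self.values.shape
        if n != len(self.sample_ids) or N != len(self.cell_ids):
            raise DimensionMismatchError("correlation matrix shape mismatch")
        if np.any(np.diff(self.group_labels) < 0):
            raise ValidationError("columns must be contiguous by group")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValidationError("Pearson entries must lie in [-1, 1]")

    @property
    def group_sizes(self):
        return np.bincount(self.group_labels)


@dataclass
class PhenotypeVector:
    """Per-sample phenotype: binary labels or survival (time, status)."""

    sample_ids: list
    mode: str  # "binary" | "survival"
    y: np.ndarray = None  # binary labels in {0,1}
    time: np.ndarray = None  # survival times > 0
    status: np.ndarray = None  # 1 = event, 0 = censored

    def __post_init__(self):
        if self.mode not in ("binary", "survival"):
            raise ValidationError(f"unknown phenotype mode {self.mode!r}")
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample IDs in phenotype table")
        if self.mode == "binary":
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape[0] != n:
                raise DimensionMismatchError("label length != sample count")
            if not np.all(np.isin(self.y, (0.0, 1.0))):
                raise ValidationError("binary labels must be 0 or 1")
        else:
            self.time = np.asarray(self.time, dtype=float)
            self.status = np.asarray(self.status, dtype=float)
            if self.time.shape[0] != n or self.status.shape[0] != n:
                raise DimensionMismatchError("time/status length != sample count")
            if np.any(self.time <= 0):
                raise ValidationError("survival times must be positive")
            if not np.all(np.isin(self.status, (0.0, 1.0))):
                raise ValidationError("status must be 0 (censored) or 1 (event)")

    @property
    def n_samples(self):
        return len(self.sample_ids)

    def failure_set(self):
        """Indices of samples with an observed event (D)."""
        if self.mode != "survival":
            raise ValidationError("failure set defined only in survival mode")
        return np.flatnonzero(self.status == 1)

    def risk_set(self, i):
        """R_i = samples with survival time >= time of sample i (closed)."""
        if self.mode != "survival":
            raise ValidationError("risk sets defined only in survival mode")
        return np.flatnonzero(self.time >= self.time[i])

    def subset(self, idx):
        idx = np.asarray(idx, dtype=int)
        ids = [self.sample_ids[i] for i in idx]
        if self.mode == "binary":
            return PhenotypeVector(ids, "binary", y=self.y[idx])
        return PhenotypeVector(
            ids, "survival", time=self.time[idx], status=self.status[idx]
        )
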