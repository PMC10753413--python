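"""Named exception types raised across the pipeline.

Every contract violation raises a distinct class so callers (and the CLI)
can map failures to actionable messages instead of pattern-matching strings.
"""


class PhenocellError(Exception):
    """Base class for all package errors."""


class InputFileError(PhenocellError):
    """Missing input file or unreadable path."""


class ParseError(PhenocellError):
    """Malformed expression/phenotype file (ragged rows, non-numeric cells)."""


class DimensionMismatchError(PhenocellError):
    """Matrix dimensions disagree with sidecar ID lists or with each other."""


class ValidationError(PhenocellError):
    """A value violates a documented precondition (labels, times, config)."""


class StageError(PhenocellError):
    """An operation received a matrix at the wrong preprocessing stage."""


class GraphError(PhenocellError):
    """SNN graph or partition precondition violated (m = 0, k too large...)."""


class SharedGeneError(PhenocellError):
    """Bulk/single-cell gene intersection too small to correlate."""


class ConvergenceError(PhenocellError):
    """Solver failed to converge; carries diagnostics."""

    def __init__(self, message, *, n_iter=None, max_change=None, kkt=None):
        super().__init__(message)
        self.n_iter = n_iter
        self.max_change = max_change
        self.kkt = kkt


class FoldError(PhenocellError):
    """Cross-validation folds could not be drawn (single-class / no-event fold)."""


class DegenerateGroupError(PhenocellError):
    """A comparison group is empty or too small for a variance estimate."""
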