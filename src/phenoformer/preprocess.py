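"""Normalization, highly-variable-gene ranking and expression binning.

Raw counts are made comparable across cells and genes in three steps:
library-size scaling of every cell to a fixed total, a log1p transform, and
per-gene division by the dispersion (variance/mean across cells of the
log-transformed values).  The normalized scale is then discretized: values
below an expressed/non-expressed threshold (default 0.1, or detected from
the first dip of the value histogram) are marked NON_EXPRESSED; the rest of
the range up to the global maximum is cut into B equal-width bins, higher
expression mapping to higher bins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .atlas import ExpressionMatrix
from .errors import ParameterError, ValidationError

logger = logging.getLogger(__name__)

#: Marker for values below the expressed threshold (later mapped to PAD).
NON_EXPRESSED: int = -1

DEFAULT_THRESHOLD: float = 0.1
DEFAULT_TARGET_TOTAL: float = 1e4


@dataclass
class GeneRanking:
    """Genes ordered by decreasing variability; the first ``T`` are retained."""

    ordered_genes: list[str]
    variability_score: np.ndarray
    T: int

    def __post_init__(self) -> None:
        if not (1 <= self.T <= len(self.ordered_genes)):
            raise ParameterError(f"T={self.T} outside [1, {len(self.ordered_genes)}]")
        if np.any(np.diff(self.variability_score) > 1e-12):
            raise ValidationError("variability scores must be non-increasing")

    @property
    def retained(self) -> list[str]:
        return self.ordered_genes[: self.T]


@dataclass
class BinningSpec:
    """Equal-width binning of normalized expression above a threshold."""

    threshold: float = DEFAULT_THRESHOLD
    B: int = 10
    bin_edges: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ParameterError("need at least 2 bins")
        if self.bin_edges is None:
            self.bin_edges = np.linspace(self.threshold, self.threshold + 1.0, self.B + 1)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if len(self.bin_edges) != self.B + 1:
            raise ParameterError("bin_edges must have B+1 entries")
        if abs(self.bin_edges[0] - self.threshold) > 1e-12:
            raise ParameterError("bin_edges must start at the threshold")
        widths = np.diff(self.bin_edges)
        if np.any(widths < 0):
            raise ParameterError("bin_edges must be non-decreasing")
        if widths.max() > 0 and np.ptp(widths) > 1e-9 * widths.max():
            raise ParameterError("bins must be equal width")


def _with_values(matrix: ExpressionMatrix, X: np.ndarray) -> ExpressionMatrix:
    return ExpressionMatrix(
        values=X,
        gene_ids=matrix.gene_ids,
        cell_ids=matrix.cell_ids,
        phenotypes=matrix.phenotypes,
        schema=matrix.schema,
    )


def library_log_normalize(
    raw: ExpressionMatrix, target_total: float | None = DEFAULT_TARGET_TOTAL
) -> ExpressionMatrix:
    """Scale each cell to ``target_total`` counts, then log1p.

    ``target_total=None`` scales to the median library size — appropriate
    for small gene panels, where a fixed 10,000-count target would inflate
    every value into the saturated region of log1p.
    """
    X = raw.dense()
    totals = X.sum(axis=1, keepdims=True)
    if target_total is None:
        target_total = float(np.median(totals[totals > 0])) or 1.0
    scale = np.divide(target_total, totals, out=np.ones_like(totals), where=totals > 0)
    return _with_values(raw, np.log1p(X * scale))


def gene_dispersion(matrix: ExpressionMatrix) -> np.ndarray:
    """Per-gene dispersion: variance/mean across cells (0 where mean is 0)."""
    X = matrix.dense()
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    return np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)


def dispersion_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Divide each gene column by its dispersion; zero-dispersion columns
    (all-zero or constant genes) are left unscaled so zeros stay zeros."""
    dispersion = gene_dispersion(matrix)
    divisor = np.where(dispersion > 0, dispersion, 1.0)
    X = matrix.dense() / divisor
    if not np.isfinite(X).all():  # pragma: no cover - defensive
        raise ValidationError("normalization produced non-finite values")
    return _with_values(matrix, X)


def normalize_expression(
    raw: ExpressionMatrix, target_total: float = DEFAULT_TARGET_TOTAL
) -> ExpressionMatrix:
    """Library-scale, log1p and dispersion-normalize an expression matrix.

    Each cell is scaled to ``target_total`` counts, values are log1p
    transformed, and each gene column is divided by its dispersion
    (variance/mean across cells of the log values).  Genes with zero
    dispersion are left unscaled, so zeros stay zeros and the output stays
    finite and non-negative.
    """
    return dispersion_scale(library_log_normalize(raw, target_total))


def rank_hvg(matrix: ExpressionMatrix, T: int) -> GeneRanking:
    """Rank genes by normalized dispersion (variance/mean), descending.

    Scoring is meaningful on the library-scaled log matrix (before the
    dispersion division, which by construction flattens variance/mean to 1);
    the pipeline ranks at that stage.  Ties are broken lexicographically by
    gene id so the ranking is deterministic for bit-identical columns.
    """
    if T <= 0 or T > matrix.n_genes:
        raise ParameterError(f"T={T} outside [1, {matrix.n_genes}]")
    X = matrix.dense()
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    score = np.divide(var, mean, out=np.zeros_like(var), where=mean > 0)
    order = sorted(range(matrix.n_genes), key=lambda j: (-score[j], matrix.gene_ids[j]))
    return GeneRanking(
        ordered_genes=[matrix.gene_ids[j] for j in order],
        variability_score=score[order],
        T=T,
    )


def detect_threshold(matrix: ExpressionMatrix, n_hist_bins: int = 50) -> float:
    """Locate the expressed/non-expressed demarcation from the value histogram.

    The histogram of positive normalized values typically shows a dense mass
    of near-zero values, a dip, then a bump of genuinely expressed values;
    the center of the first interior local minimum is returned.  Without an
    interior dip (or without positive values at all) the conventional 0.1
    default is returned.
    """
    if n_hist_bins < 3:
        raise ParameterError("need at least 3 histogram bins")
    X = matrix.values.data if sp.issparse(matrix.values) else matrix.dense().ravel()
    positive = np.asarray(X[X > 0], dtype=float)
    if positive.size == 0:
        warnings.warn("no positive values; falling back to default threshold 0.1")
        return DEFAULT_THRESHOLD
    counts, edges = np.histogram(positive, bins=n_hist_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    for i in range(1, n_hist_bins - 1):
        if counts[i] < counts[i - 1] and counts[i] <= counts[i + 1]:
            # a genuine demarcation dip, not sampling noise or the far tail:
            # the bin must fall well below substantial modes on both sides
            left, right = counts[:i].max(), counts[i + 1 :].max()
            if (
                counts[i] < 0.5 * min(left, right)
                and right >= 0.1 * counts.max()
            ):
                return float(centers[i])
    return DEFAULT_THRESHOLD


def build_binning_spec(
    matrix: ExpressionMatrix, threshold: float = DEFAULT_THRESHOLD, B: int = 10
) -> BinningSpec:
    """Equal-width bin edges spanning [threshold, global max] of the matrix."""
    global_max = float(matrix.dense().max())
    hi = global_max if global_max > threshold else threshold + 1e-6
    return BinningSpec(threshold=threshold, B=B,
                       bin_edges=np.linspace(threshold, hi, B + 1))


def bin_expression(values: np.ndarray, spec: BinningSpec) -> np.ndarray:
    """Map normalized values to bin indices in [0, B-1] or NON_EXPRESSED (-1).

    Values below the threshold are NON_EXPRESSED; the top bin's right edge is
    inclusive; values above the top edge (possible when the spec was built on
    a different split) clamp to bin B-1 with a logged count.  The mapping is
    monotone non-decreasing in the value.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("values must be finite")
    width = (spec.bin_edges[-1] - spec.bin_edges[0]) / spec.B
    idx = np.floor((values - spec.threshold) / width).astype(int)
    n_clamped = int((values > spec.bin_edges[-1]).sum())
    if n_clamped:
        logger.info("clamped %d value(s) above the top bin edge to bin B-1", n_clamped)
    idx = np.clip(idx, 0, spec.B - 1)
    return np.where(values < spec.threshold, NON_EXPRESSED, idx)
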