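"""Expression-table preprocessing and sample-similarity construction.

The downstream labeling model consumes nothing but an N x N sample
similarity matrix, so everything in this module is about producing one:
microarray intensity cleaning, phenotype-correlated biomarker selection,
pairwise Pearson similarity, second-order (correlation-of-correlations)
similarity, and the linear [-1, 1] -> [0, 1] rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# expression scales
RAW_INTENSITY = "raw_intensity"
LOG10 = "log10"

# similarity scales
PEARSON_RAW = "pearson_raw"
UNIT = "unit"

SYMMETRY_TOL = 1e-10


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table with identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_genes, n_samples)
        Expression values; must be finite.
    gene_ids, sample_ids : list of str
        Row / column identifiers, lengths matching ``values``.
    scale : {"raw_intensity", "log10"}
        Whether values are raw intensities or log10-transformed.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    scale: str = RAW_INTENSITY

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        n, m = self.values.shape
        if len(self.gene_ids) != n:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {n} rows")
        if len(self.sample_ids) != m:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {m} columns")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        if self.scale not in (RAW_INTENSITY, LOG10):
            raise ValueError(f"unknown expression scale {self.scale!r}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class SimilarityMatrix:
    """Symmetric N x N sample-similarity scores with a scale tag.

    ``scale`` is ``"pearson_raw"`` for signed correlations in [-1, 1]
    (noisy simulated matrices may exceed the nominal range) or ``"unit"``
    after the linear map to [0, 1].  Symmetry is enforced to 1e-10 and
    then made exact.
    """

    values: np.ndarray
    sample_ids: list[str]
    scale: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        n = self.values.shape[0]
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")
        if self.scale not in (PEARSON_RAW, UNIT):
            raise ValueError(f"unknown similarity scale {self.scale!r}")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        if asym > SYMMETRY_TOL:
            raise ValueError(f"similarity matrix asymmetric by {asym:g}")
        self.values = (self.values + self.values.T) / 2.0
        if self.scale == UNIT:
            if self.values.min() < -1e-12 or self.values.max() > 1 + 1e-12:
                raise ValueError("unit-scale similarities must lie in [0, 1]")
            self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def submatrix(self, indices) -> "SimilarityMatrix":
        """Restriction to the given sample indices (order preserved)."""
        idx = np.asarray(indices, dtype=int)
        return SimilarityMatrix(
            self.values[np.ix_(idx, idx)],
            [self.sample_ids[i] for i in idx],
            self.scale,
        )


def preprocess_expression(
    expr: ExpressionMatrix,
    ceiling: float = 16000.0,
    floor: float = 100.0,
    fold_min: float = 5.0,
    diff_min: float = 500.0,
) -> ExpressionMatrix:
    """Clean a raw-intensity table: clip, drop uninformative genes, log10.

    Values are clipped into ``[floor, ceiling]``; a gene is removed when,
    across samples after clipping, ``max/min <= fold_min`` OR
    ``max - min <= diff_min``; surviving values are log10-transformed.

    Returns a new :class:`ExpressionMatrix` with ``scale="log10"``.

    Raises
    ------
    ValueError
        If the input is not raw-intensity scale, the thresholds are
        inconsistent, or no gene survives both filters.
    """
    if expr.scale != RAW_INTENSITY:
        raise ValueError("preprocess_expression expects raw intensities")
    if floor <= 0:
        raise ValueError("floor must be positive (log transform follows)")
    if ceiling <= floor:
        raise ValueError("ceiling must exceed floor")

    clipped = np.clip(expr.values, floor, ceiling)
    gmax = clipped.max(axis=1)
    gmin = clipped.min(axis=1)
    drop = (gmax / gmin <= fold_min) | (gmax - gmin <= diff_min)
    keep = ~drop
    if not keep.any():
        raise ValueError(
            "no genes survive filtering: every gene has "
            f"max/min <= {fold_min} or max - min <= {diff_min}"
        )
    n_dropped = int(drop.sum())
    if n_dropped:
        logger.info("filtered %d/%d genes", n_dropped, expr.n_genes)
    return ExpressionMatrix(
        np.log10(clipped[keep]),
        [g for g, k in zip(expr.gene_ids, keep) if k],
        list(expr.sample_ids),
        scale=LOG10,
    )


def select_biomarkers(
    expr: ExpressionMatrix,
    phenotype,
    r_threshold: float = 0.6,
    top_k: int | None = None,
) -> np.ndarray:
    """Genes whose Pearson correlation with a 0/1 phenotype exceeds
    ``r_threshold`` in absolute value.

    Returns gene indices sorted by descending ``|r|`` (ties by index).
    Zero-variance genes have undefined correlation and are silently
    excluded (a note is logged).  If ``top_k`` is given, only that many
    of the selected genes are returned.
    """
    y = np.asarray(phenotype, dtype=float).ravel()
    if y.size != expr.n_samples:
        raise ValueError("phenotype length must equal number of samples")
    if np.unique(y).size < 2:
        raise ValueError("phenotype must contain both classes")
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")

    x = expr.values
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    defined = sx > 0
    n_undef = int((~defined).sum())
    if n_undef:
        logger.info("excluded %d zero-variance genes from biomarker selection", n_undef)
    r = np.zeros(expr.n_genes)
    r[defined] = (xc[defined] @ yc) / (sx[defined] * sy)
    hits = np.flatnonzero(defined & (np.abs(r) > r_threshold))
    order = np.lexsort((hits, -np.abs(r[hits])))
    selected = hits[order]
    if top_k is not None:
        selected = selected[:top_k]
    return selected


def pearson_similarity(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Pairwise Pearson correlation of sample columns over genes.

    The estimator normalization (1/n vs 1/(n-1)) cancels in the
    correlation ratio, so the result is estimator-independent.
    """
    if expr.n_genes < 2:
        raise ValueError("need at least 2 genes to correlate samples")
    std = expr.values.std(axis=0)
    bad = np.flatnonzero(std == 0)
    if bad.size:
        names = ", ".join(expr.sample_ids[i] for i in bad)
        raise ValueError(f"zero-variance sample column(s): {names}")
    r = np.corrcoef(expr.values, rowvar=False)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(r, list(expr.sample_ids), PEARSON_RAW)


def second_order_similarity(first_order: SimilarityMatrix) -> SimilarityMatrix:
    """Pearson correlation of the rows of a first-order similarity matrix.

    Row i (sample i's similarity profile against every sample, including
    itself) is treated as sample i's feature vector; the result is a
    globally informed similarity.
    """
    if first_order.n < 3:
        raise ValueError("second-order similarity needs at least 3 samples")
    v = first_order.values
    const = np.flatnonzero(np.ptp(v, axis=1) == 0)
    if const.size:
        names = ", ".join(first_order.sample_ids[i] for i in const)
        raise ValueError(f"constant similarity row(s), correlation undefined: {names}")
    r = np.corrcoef(v)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(r, list(first_order.sample_ids), PEARSON_RAW)


def rescale_unit(sim: SimilarityMatrix) -> SimilarityMatrix:
    """Linear map of signed correlations [-1, 1] onto [0, 1]: s' = (s+1)/2.

    Refuses unit-scale input so a matrix can never be mapped twice.
    """
    if sim.scale != PEARSON_RAW:
        raise ValueError("similarity is already on the unit scale")
    vals = (sim.values + 1.0) / 2.0
    return SimilarityMatrix(np.clip(vals, 0.0, 1.0), list(sim.sample_ids), UNIT)
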