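"""Synthetic inputs and benchmark sweeps.

Two generator families: block-structured similarity matrices (within-class
score 1, between-class 0, symmetric Gaussian noise) and graphs of fully
connected components whose adjacency rows yield a Pearson similarity.
Benchmark drivers score single-split discovery accuracy over a
(noise, class-size-ratio) grid and prediction accuracy as a function of
the number of known labels per class.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .discovery import split_cluster
from .prediction import KnownLabels, predict_binary
from .preprocess import PEARSON_RAW, SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwoClassSpec:
    """Two-class noisy block-similarity design.

    One class has ``size_small`` samples, the other ``ratio``-fold as
    many; ``sigma`` is the standard deviation of the zero-mean Gaussian
    noise added to the off-diagonal scores.
    """

    size_small: int = 5
    ratio: int = 1
    sigma: float = 0.0
    reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_small < 1 or self.ratio < 1:
            raise ValueError("class sizes must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class GraphSpec:
    """Graph of fully connected components with optional cross links."""

    component_sizes: tuple[int, ...]
    inter_links: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "component_sizes", tuple(int(s) for s in self.component_sizes))
        if any(s < 2 for s in self.component_sizes):
            raise ValueError("component sizes must be >= 2")
        if self.inter_links < 0:
            raise ValueError("inter_links must be >= 0")


def _block_base(sizes, between: float | np.ndarray = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free block matrix (within 1, between as given) plus labels."""
    sizes = [int(s) for s in sizes]
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    if np.isscalar(between):
        bmat = np.full((len(sizes), len(sizes)), float(between))
    else:
        bmat = np.asarray(between, dtype=float)
    base = np.where(labels[:, None] == labels[None, :], 1.0, bmat[labels[:, None], labels[None, :]])
    np.fill_diagonal(base, 1.0)
    return base, labels


def _add_symmetric_noise(base: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise drawn on the strict upper triangle and mirrored;
    the diagonal stays noise-free."""
    n = base.shape[0]
    noise = rng.normal(0.0, sigma, size=(n, n))
    upper = np.triu(noise, k=1)
    return base + upper + upper.T


def make_block_similarity(
    sizes,
    between: float | np.ndarray = 0.0,
    sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[SimilarityMatrix, np.ndarray]:
    """General k-class noisy block similarity; returns (matrix, labels)."""
    rng = np.random.default_rng(rng)
    base, labels = _block_base(sizes, between)
    values = _add_symmetric_noise(base, sigma, rng) if sigma > 0 else base
    ids = [f"s{i + 1}" for i in range(base.shape[0])]
    return SimilarityMatrix(values, ids, PEARSON_RAW), labels


def make_two_class_similarity(
    spec: TwoClassSpec, rng: np.random.Generator | None = None
) -> tuple[SimilarityMatrix, np.ndarray]:
    """Two-class block similarity per ``spec``; returns (matrix, labels).

    With no explicit ``rng`` a fresh generator is seeded from
    ``spec.seed``, so the same spec always yields the same matrix.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    return make_block_similarity(
        (spec.size_small, spec.size_small * spec.ratio), 0.0, spec.sigma, rng
    )


def make_component_graph(
    spec: GraphSpec, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Adjacency of complete components plus random between-component edges."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    base, labels = _block_base(spec.component_sizes, 0.0)
    adj = base.astype(int)
    np.fill_diagonal(adj, 0)
    cross = [
        (i, j)
        for i, j in itertools.combinations(range(adj.shape[0]), 2)
        if labels[i] != labels[j]
    ]
    if spec.inter_links > len(cross):
        raise ValueError(
            f"requested {spec.inter_links} inter-links but only "
            f"{len(cross)} cross-component pairs exist"
        )
    if spec.inter_links:
        for k in rng.choice(len(cross), size=spec.inter_links, replace=False):
            i, j = cross[k]
            adj[i, j] = adj[j, i] = 1
    return adj


def graph_similarity(adjacency: np.ndarray) -> SimilarityMatrix:
    """Pearson correlation of adjacency rows (connection vectors)."""
    adj = np.asarray(adjacency, dtype=float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if np.trace(np.abs(adj)) != 0:
        raise ValueError("adjacency diagonal must be zero")
    if not np.isin(adj, (0.0, 1.0)).all():
        raise ValueError("adjacency must be 0/1")
    isolated = np.flatnonzero(adj.sum(axis=1) == 0)
    if isolated.size:
        nodes = ", ".join(str(i + 1) for i in isolated)
        raise ValueError(f"isolated node(s) with undefined correlation: {nodes}")
    r = np.corrcoef(adj)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    ids = [str(i + 1) for i in range(adj.shape[0])]
    return SimilarityMatrix(r, ids, PEARSON_RAW)


def clustering_accuracy(predicted, truth) -> float:
    """Best agreement fraction over all bijections of cluster ids.

    Solved as an optimal assignment on the contingency table, so label
    permutations do not matter.
    """
    pred = np.asarray(predicted).ravel()
    true = np.asarray(truth).ravel()
    if pred.size != true.size:
        raise ValueError("label vectors must have equal length")
    if pred.size == 0:
        raise ValueError("empty label vectors")
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(true, return_inverse=True)
    table = np.zeros((ti.max() + 1, pi.max() + 1), dtype=int)
    np.add.at(table, (ti, pi), 1)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum()) / pred.size


def _single_split_labels(sim: SimilarityMatrix) -> np.ndarray:
    zero, one, _ = split_cluster(sim)
    labels = np.zeros(sim.n, dtype=int)
    labels[one] = 1
    return labels


def run_discovery_benchmark(specs) -> pd.DataFrame:
    """Mean single-split discovery accuracy per (ratio, sigma) cell.

    For each spec, ``reps`` matrices are generated from one generator
    seeded by ``spec.seed``; each gets one most-dissimilar-seeded split
    and is scored by :func:`clustering_accuracy` against the planted
    labels.  Returns a table with per-cell replicate counts and standard
    errors.
    """
    rows = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        accs = np.empty(spec.reps)
        for rep in range(spec.reps):
            sim, truth = make_two_class_similarity(spec, rng)
            accs[rep] = clustering_accuracy(_single_split_labels(sim), truth)
        rows.append(
            {
                **asdict(spec),
                "mean_accuracy": float(accs.mean()),
                "sem": float(accs.std(ddof=1) / np.sqrt(spec.reps)) if spec.reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


def run_prediction_sweep(
    source,
    known_grid,
    reps: int = 100,
    seed: int = 0,
    cutoff: float = 0.5,
    truth=None,
) -> pd.DataFrame:
    """Mean two-class prediction accuracy per (k0, k1) known-label cell.

    ``source`` is either a fixed ``(SimilarityMatrix, truth)`` problem
    (pass the matrix with ``truth=``) or a callable ``rng -> (sim,
    truth)`` generating a fresh problem per replicate.  Each replicate
    samples k0/k1 known labels uniformly within each class (stratified by
    class), predicts the rest, and scores accuracy on the unknown
    samples only (1.0 when none remain).  Cells asking for more knowns
    than a class holds are skipped with a warning.
    """
    if callable(source):
        factory = source
    else:
        sim_fixed = source
        if truth is None:
            raise ValueError("a fixed similarity source needs truth labels")
        truth_fixed = np.asarray(truth)

        def factory(_rng):
            return sim_fixed, truth_fixed

    rng = np.random.default_rng(seed)
    rows = []
    for k0, k1 in known_grid:
        accs = []
        skipped = False
        for _ in range(reps):
            sim, labels = factory(rng)
            labels = np.asarray(labels)
            classes = np.unique(labels)
            if classes.size != 2:
                raise ValueError("prediction sweep is two-class")
            idx0 = np.flatnonzero(labels == classes[0])
            idx1 = np.flatnonzero(labels == classes[1])
            if k0 > idx0.size or k1 > idx1.size:
                logger.warning("cell (k0=%d, k1=%d) exceeds class sizes; skipped", k0, k1)
                skipped = True
                break
            known_idx = np.concatenate(
                [rng.choice(idx0, size=k0, replace=False), rng.choice(idx1, size=k1, replace=False)]
            )
            known = KnownLabels.from_pairs(
                [(sim.sample_ids[i], str(labels[i])) for i in known_idx],
                classes=[str(c) for c in classes],
            )
            pred, _ = predict_binary(sim, known, cutoff=cutoff)
            mask = np.ones(sim.n, dtype=bool)
            mask[known_idx] = False
            if mask.sum() == 0:
                accs.append(1.0)
            else:
                accs.append(float(np.mean(pred[mask] == labels[mask].astype(str))))
        if skipped:
            continue
        accs = np.asarray(accs)
        rows.append(
            {
                "k0": int(k0),
                "k1": int(k1),
                "reps": reps,
                "mean_accuracy": float(accs.mean()),
                "sem": float(accs.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=["k0", "k1", "reps", "mean_accuracy", "sem"])
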