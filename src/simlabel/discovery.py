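"""Unsupervised class discovery by recursive binary splitting.

Seeds for each split come from the most-dissimilar assumption: the least
similar pair of samples must belong to different classes.  A cluster is
split while its inner minimum similarity sits below a tolerance
threshold; the recursion yields a binary tree whose leaves partition the
samples.  Splits can transiently lump seed-disconnected samples into a
pseudo-cluster; further recursion resolves it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PEARSON_RAW, UNIT, SimilarityMatrix
from .solver import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    LabelProblem,
    LabelSolution,
    binarize,
    solve_iterative,
)

DEFAULT_MAX_POWER = 5
TIE_TOL = 1e-9


@dataclass
class ClusterNode:
    """One node of the divisive cluster tree.

    ``members`` are global sample indices; ``seed_pair`` is the
    (class-zero, class-one) seed pair used to split this node, or None
    for leaves; ``inner_min_similarity`` is the minimum off-diagonal
    similarity among members on the criterion scale (+inf for
    singletons).
    """

    members: tuple[int, ...]
    inner_min_similarity: float
    seed_pair: tuple[int, int] | None = None
    children: tuple["ClusterNode", "ClusterNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list["ClusterNode"]:
        if self.is_leaf:
            return [self]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass
class ClusterTree:
    """Binary tree over sample indices recording every recursive split."""

    root: ClusterNode
    sample_ids: list[str]
    threshold: float

    def leaves(self) -> list[ClusterNode]:
        return self.root.leaves()

    def leaf_members(self) -> list[tuple[int, ...]]:
        return [leaf.members for leaf in self.leaves()]

    def leaf_paths(self) -> list[tuple[ClusterNode, str]]:
        """Leaves with their root-to-leaf path bitstrings (0=left, 1=right)."""
        out: list[tuple[ClusterNode, str]] = []

        def walk(node: ClusterNode, path: str) -> None:
            if node.is_leaf:
                out.append((node, path))
            else:
                walk(node.children[0], path + "0")
                walk(node.children[1], path + "1")

        walk(self.root, "")
        return out

    def assignments(self) -> pd.DataFrame:
        """Flat table (sample_id, leaf, path) in leaf order."""
        rows = []
        for leaf_id, (leaf, path) in enumerate(self.leaf_paths()):
            for i in leaf.members:
                rows.append((self.sample_ids[i], leaf_id, path))
        return pd.DataFrame(rows, columns=["sample_id", "leaf", "path"])


def _members_array(sim: SimilarityMatrix, members) -> np.ndarray:
    if members is None:
        return np.arange(sim.n)
    m = np.unique(np.asarray(members, dtype=int))
    if m.size and (m.min() < 0 or m.max() >= sim.n):
        raise ValueError("member indices out of range")
    return m


def find_seed_pair(
    sim: SimilarityMatrix,
    members=None,
    max_power: int = DEFAULT_MAX_POWER,
    tie_tol: float = TIE_TOL,
) -> tuple[int, int]:
    """Most-dissimilar pair within ``members``; first index seeds Class Zero.

    Returns the pair attaining the minimum off-diagonal similarity.  Ties
    are re-ranked by the entries of successive powers S^2, S^3, ... of the
    member-restricted matrix (restricted to the tied pairs) up to
    ``max_power``; a residual tie falls back to the lexicographically
    smallest pair, with a degeneracy warning when every power left more
    than one candidate.
    """
    m = _members_array(sim, members)
    k = m.size
    if k < 2:
        raise ValueError("need at least 2 members to pick a seed pair")
    sub = sim.values[np.ix_(m, m)]
    iu, ju = np.triu_indices(k, 1)  # row-major == lexicographic order
    vals = sub[iu, ju]
    vmin = vals.min()
    tied = np.flatnonzero(vals <= vmin + tie_tol)
    power_mat = sub
    power = 1
    while tied.size > 1 and power < max_power:
        power += 1
        power_mat = power_mat @ sub
        pv = power_mat[iu[tied], ju[tied]]
        pmin = pv.min()
        tol = tie_tol * max(1.0, abs(pmin))
        tied = tied[pv <= pmin + tol]
    if tied.size > 1:
        warnings.warn(
            f"{tied.size} seed pairs still tied after S^{max_power}; "
            "using the lexicographically smallest",
            RuntimeWarning,
            stacklevel=2,
        )
    t = tied[0]
    return int(m[iu[t]]), int(m[ju[t]])


def split_cluster(
    sim: SimilarityMatrix,
    members=None,
    seed_pair: tuple[int, int] | None = None,
    cutoff: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    max_power: int = DEFAULT_MAX_POWER,
    negatives: str = "clip",
) -> tuple[np.ndarray, np.ndarray, LabelSolution]:
    """One binary split of ``members`` via the labeling model.

    Seeds default to the most-dissimilar pair.  The solver runs on the
    member-restricted similarity in permissive mode (signed scores are
    clipped at zero) and the continuous labels are thresholded at
    ``cutoff``.  Returns (class-zero members, class-one members,
    solution); either side may be a pseudo-cluster holding
    seed-disconnected samples that kept label 0.
    """
    m = _members_array(sim, members)
    if m.size < 2:
        raise ValueError("cannot split fewer than 2 members")
    if seed_pair is None:
        seed_pair = find_seed_pair(sim, m, max_power=max_power)
    a, b = seed_pair
    pos = {int(g): i for i, g in enumerate(m)}
    if a not in pos or b not in pos:
        raise ValueError("seed pair must belong to the member set")
    sub = sim.submatrix(m)
    problem = LabelProblem(sub, [pos[a]], [pos[b]], negatives=negatives)
    sol = solve_iterative(problem, tol=tol, max_iter=max_iter)
    labels = binarize(sol, cutoff)
    return m[labels == 0], m[labels == 1], sol


def min_inner_similarity(sim: SimilarityMatrix, members=None) -> float:
    """Minimum off-diagonal similarity among members; +inf for singletons."""
    m = _members_array(sim, members)
    if m.size < 1:
        raise ValueError("empty member set")
    if m.size == 1:
        return float("inf")
    sub = sim.values[np.ix_(m, m)]
    iu, ju = np.triu_indices(m.size, 1)
    return float(sub[iu, ju].min())


def _criterion_values(sim: SimilarityMatrix, criterion_scale: str) -> np.ndarray:
    if criterion_scale == "input":
        return sim.values
    if criterion_scale == "unit":
        return (sim.values + 1.0) / 2.0 if sim.scale == PEARSON_RAW else sim.values
    if criterion_scale == "raw":
        return 2.0 * sim.values - 1.0 if sim.scale == UNIT else sim.values
    raise ValueError(f"unknown criterion scale {criterion_scale!r}")


def discover(
    sim: SimilarityMatrix,
    threshold: float,
    criterion_scale: str = "input",
    cutoff: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    max_power: int = DEFAULT_MAX_POWER,
) -> ClusterTree:
    """Recursive class discovery with the minimum-similarity stopping rule.

    Every node whose inner minimum similarity (evaluated on
    ``criterion_scale``: the input scale by default, or forced to the
    signed/unit scale) falls below ``threshold`` is split; leaves
    partition the sample set.  The optimization itself always consumes
    non-negative similarities (permissive clipping).  Entirely
    deterministic for a given similarity matrix.
    """
    if sim.n < 2:
        raise ValueError("need at least 2 samples to cluster")
    crit = SimilarityMatrix(
        _criterion_values(sim, criterion_scale), list(sim.sample_ids), sim.scale
    )
    max_depth = sim.n  # recursion sanity cap; each split strictly shrinks

    def build(members: np.ndarray, depth: int) -> ClusterNode:
        if depth > max_depth:  # pragma: no cover - unreachable by construction
            raise RuntimeError("cluster recursion exceeded sample count")
        imin = min_inner_similarity(crit, members)
        node = ClusterNode(tuple(int(i) for i in members), imin)
        if members.size >= 2 and imin < threshold:
            pair = find_seed_pair(sim, members, max_power=max_power)
            zero, one, _ = split_cluster(
                sim,
                members,
                seed_pair=pair,
                cutoff=cutoff,
                tol=tol,
                max_iter=max_iter,
            )
            node.seed_pair = pair
            node.children = (build(zero, depth + 1), build(one, depth + 1))
        return node

    return ClusterTree(build(np.arange(sim.n), 0), list(sim.sample_ids), threshold)


def cluster_summary(sim: SimilarityMatrix, tree: ClusterTree) -> pd.DataFrame:
    """Mean similarity within and between every pair of tree leaves.

    Rows carry (leaf_i, leaf_j, mean_similarity); within-leaf means
    (leaf_i == leaf_j) average the off-diagonal block and are NaN for
    singletons.
    """
    leaves = tree.leaf_members()
    if len(leaves) < 2:
        raise ValueError("cluster summary needs at least 2 leaves")
    rows = []
    for i, mi in enumerate(leaves):
        for j in range(i, len(leaves)):
            mj = leaves[j]
            block = sim.values[np.ix_(mi, mj)]
            if i == j:
                k = len(mi)
                mean = float("nan") if k < 2 else float(
                    (block.sum() - np.trace(block)) / (k * (k - 1))
                )
            else:
                mean = float(block.mean())
            rows.append((i, j, mean))
    return pd.DataFrame(rows, columns=["leaf_i", "leaf_j", "mean_similarity"])
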