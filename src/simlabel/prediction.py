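"""Semi-supervised class prediction from partially labeled samples.

With gold-standard labels for some samples, the seed sets are known and
the labeling model applies directly.  Multi-class problems are handled
three ways: recursion down a binary tree over class ids, one-vs-all
scoring, and one-vs-one voting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import reduce

import numpy as np

from .preprocess import SimilarityMatrix
from .solver import (
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    LabelProblem,
    LabelSolution,
    binarize,
    solve_iterative,
)

logger = logging.getLogger(__name__)


@dataclass
class KnownLabels:
    """Partial gold-standard labeling: sample_id -> class_id.

    ``classes`` fixes the class order used for tie-breaking and for the
    default left-deep class tree.
    """

    assignments: dict[str, str]
    classes: list[str]

    def __post_init__(self) -> None:
        if not self.assignments:
            raise ValueError("no known labels given")
        seen = set(self.assignments.values())
        missing = [c for c in self.classes if c not in seen]
        if missing:
            raise ValueError(f"classes without any labeled sample: {missing}")
        extra = seen - set(self.classes)
        if extra:
            raise ValueError(f"labels outside the class list: {sorted(extra)}")
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("duplicate class ids")

    @classmethod
    def from_pairs(cls, pairs, classes=None) -> "KnownLabels":
        """Build from (sample_id, class_id) pairs, rejecting conflicts."""
        assignments: dict[str, str] = {}
        order: list[str] = []
        for sample_id, class_id in pairs:
            sample_id, class_id = str(sample_id), str(class_id)
            if sample_id in assignments and assignments[sample_id] != class_id:
                raise ValueError(
                    f"sample {sample_id!r} labeled with both "
                    f"{assignments[sample_id]!r} and {class_id!r}"
                )
            assignments[sample_id] = class_id
            if class_id not in order:
                order.append(class_id)
        return cls(assignments, list(classes) if classes is not None else order)

    def indices_by_class(self, sample_ids: list[str]) -> dict[str, np.ndarray]:
        """Map each class to the indices of its labeled samples."""
        pos = {s: i for i, s in enumerate(sample_ids)}
        missing = [s for s in self.assignments if s not in pos]
        if missing:
            raise ValueError(f"labeled samples absent from similarity matrix: {missing}")
        out: dict[str, list[int]] = {c: [] for c in self.classes}
        for s, c in self.assignments.items():
            out[c].append(pos[s])
        return {c: np.array(sorted(v), dtype=int) for c, v in out.items()}


@dataclass(frozen=True)
class ClassTree:
    """Binary tree whose leaves are class ids."""

    class_id: str | None = None
    children: tuple["ClassTree", "ClassTree"] | None = None

    def __post_init__(self) -> None:
        if (self.class_id is None) == (self.children is None):
            raise ValueError("a node is either a class leaf or has two children")

    @classmethod
    def leaf(cls, class_id: str) -> "ClassTree":
        return cls(class_id=str(class_id))

    @classmethod
    def node(cls, left: "ClassTree", right: "ClassTree") -> "ClassTree":
        return cls(children=(left, right))

    @classmethod
    def from_nested(cls, spec) -> "ClassTree":
        """Build from nested 2-tuples/lists of class ids."""
        if isinstance(spec, (tuple, list)):
            if len(spec) != 2:
                raise ValueError("class tree nodes must be binary")
            return cls.node(cls.from_nested(spec[0]), cls.from_nested(spec[1]))
        return cls.leaf(spec)

    @classmethod
    def left_deep(cls, classes) -> "ClassTree":
        leaves = [cls.leaf(c) for c in classes]
        if not leaves:
            raise ValueError("no classes")
        return reduce(cls.node, leaves)

    def leaves(self) -> list[str]:
        if self.children is None:
            return [self.class_id]
        return self.children[0].leaves() + self.children[1].leaves()


def _solve(sim, set_a, set_b, tol, max_iter, negatives) -> LabelSolution:
    problem = LabelProblem(sim, set_a, set_b, negatives=negatives)
    return solve_iterative(problem, tol=tol, max_iter=max_iter)


def predict_binary(
    sim: SimilarityMatrix,
    known: KnownLabels,
    cutoff: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    negatives: str = "clip",
) -> tuple[np.ndarray, LabelSolution]:
    """Two-class prediction: seeds from the known labels, then one solve.

    Returns (class ids per sample, solution).  Known samples keep their
    labels exactly (they are the constraint seeds).
    """
    if len(known.classes) != 2:
        raise ValueError("predict_binary needs exactly 2 classes")
    by_class = known.indices_by_class(sim.sample_ids)
    c0, c1 = known.classes
    sol = _solve(sim, by_class[c0], by_class[c1], tol, max_iter, negatives)
    calls = binarize(sol, cutoff)
    labels = np.where(calls == 0, c0, c1).astype(object)
    labels[by_class[c0]] = c0
    labels[by_class[c1]] = c1
    return labels, sol


def predict_multiclass_tree(
    sim: SimilarityMatrix,
    known: KnownLabels,
    tree: ClassTree | None = None,
    cutoff: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    negatives: str = "clip",
) -> np.ndarray:
    """Recursive prediction down a binary tree over class ids.

    At each internal node the known samples under the left subtree seed
    Class Zero and those under the right seed Class One; unknowns are
    thresholded and passed down the matching branch until a class leaf is
    reached.  Without an explicit tree a left-deep tree in class order is
    used (logged) — any tree works when classes are unrelated, but a tree
    contradicting real class structure degrades accuracy.
    """
    if tree is None:
        tree = ClassTree.left_deep(known.classes)
        logger.warning("no class tree given; using left-deep tree over %s", known.classes)
    tree_classes = tree.leaves()
    if sorted(tree_classes) != sorted(known.classes):
        raise ValueError("class tree leaves must match the known classes exactly")
    by_class = known.indices_by_class(sim.sample_ids)
    labels = np.empty(sim.n, dtype=object)

    def recurse(node: ClassTree, members: np.ndarray) -> None:
        if node.children is None:
            labels[members] = node.class_id
            return
        left, right = node.children
        left_classes, right_classes = set(left.leaves()), set(right.leaves())
        member_set = set(members.tolist())
        set_a = [i for c in sorted(left_classes) for i in by_class[c] if i in member_set]
        set_b = [i for c in sorted(right_classes) for i in by_class[c] if i in member_set]
        if not set_a or not set_b:
            raise ValueError(
                f"tree node ({'+'.join(sorted(left_classes))} | "
                f"{'+'.join(sorted(right_classes))}) has an empty seed side"
            )
        pos = {int(g): i for i, g in enumerate(members)}
        sub = sim.submatrix(members)
        sol = _solve(
            sub, [pos[i] for i in set_a], [pos[i] for i in set_b], tol, max_iter, negatives
        )
        calls = binarize(sol, cutoff)
        recurse(left, members[calls == 0])
        recurse(right, members[calls == 1])

    recurse(tree, np.arange(sim.n))
    for c, idx in by_class.items():  # seeds are exact, but make the contract explicit
        labels[idx] = c
    return labels


def _class_scores(sim, known, tol, max_iter, negatives) -> np.ndarray:
    """One-vs-all membership scores: column c is f from solving with the
    class-c seeds as Class One and all other known samples as Class Zero."""
    by_class = known.indices_by_class(sim.sample_ids)
    scores = np.empty((sim.n, len(known.classes)))
    for k, c in enumerate(known.classes):
        others = np.concatenate([by_class[o] for o in known.classes if o != c])
        sol = _solve(sim, others, by_class[c], tol, max_iter, negatives)
        scores[:, k] = sol.f
    return scores


def predict_one_vs_all(
    sim: SimilarityMatrix,
    known: KnownLabels,
    cutoff: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    negatives: str = "clip",
) -> np.ndarray:
    """One-vs-all prediction: argmax over per-class membership scores.

    Each class is scored by solving with its known samples as Class One
    against all other known samples; ties go to the earlier class in
    ``known.classes`` (logged).  ``cutoff`` is accepted for interface
    symmetry but the argmax rule does not use it.
    """
    del cutoff
    scores = _class_scores(sim, known, tol, max_iter, negatives)
    best = np.argmax(scores, axis=1)  # argmax takes the first max: class-order ties
    n_tied = int(np.sum(np.sum(scores == scores.max(axis=1, keepdims=True), axis=1) > 1))
    if n_tied:
        logger.info("%d samples had tied one-vs-all scores; first class wins", n_tied)
    labels = np.array([known.classes[k] for k in best], dtype=object)
    by_class = known.indices_by_class(sim.sample_ids)
    for c, idx in by_class.items():
        labels[idx] = c
    return labels


def predict_one_vs_one(
    sim: SimilarityMatrix,
    known: KnownLabels,
    cutoff: float = 0.5,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    negatives: str = "clip",
) -> np.ndarray:
    """One-vs-one prediction by pairwise voting.

    Every class pair is solved on its own known samples plus all unknown
    samples; each unknown votes for the winning class of each duel and
    takes the class with most votes (ties by class order).
    """
    by_class = known.indices_by_class(sim.sample_ids)
    classes = known.classes
    labeled = np.concatenate([by_class[c] for c in classes])
    unknown = np.setdiff1d(np.arange(sim.n), labeled)
    votes = np.zeros((sim.n, len(classes)), dtype=int)
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            ci, cj = classes[i], classes[j]
            members = np.sort(np.concatenate([by_class[ci], by_class[cj], unknown]))
            pos = {int(g): k for k, g in enumerate(members)}
            sub = sim.submatrix(members)
            sol = _solve(
                sub,
                [pos[a] for a in by_class[ci]],
                [pos[b] for b in by_class[cj]],
                tol,
                max_iter,
                negatives,
            )
            calls = binarize(sol, cutoff)
            for local, g in enumerate(members):
                votes[g, i if calls[local] == 0 else j] += 1
    best = np.argmax(votes, axis=1)
    labels = np.array([classes[k] for k in best], dtype=object)
    for c, idx in by_class.items():
        labels[idx] = c
    return labels


def learn_cutoff(
    sim: SimilarityMatrix,
    known: KnownLabels,
    grid=None,
    n_folds: int = 5,
    seed: int = 0,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    negatives: str = "clip",
) -> float:
    """Learn a binarization cutoff by k-fold cross-validation (binary only).

    Each fold holds out part of the known labels, solves with the rest,
    and scores every cutoff in ``grid`` (default 0.05..0.95 step 0.05) on
    the held-out samples.  Returns the cutoff with highest mean accuracy;
    ties prefer the value closest to 0.5.
    """
    if len(known.classes) != 2:
        raise ValueError("cutoff learning is defined for binary problems")
    if grid is None:
        grid = np.round(np.arange(0.05, 0.951, 0.05), 2)
    grid = np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("cutoff grid must lie strictly inside (0, 1)")
    by_class = known.indices_by_class(sim.sample_ids)
    c0, c1 = known.classes
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in (c0, c1):  # stratified assignment of labeled samples to folds
        idx = by_class[c].copy()
        rng.shuffle(idx)
        for k, i in enumerate(idx):
            folds[k % n_folds].append(int(i))
    correct = np.zeros(grid.size)
    total = 0
    for fold in folds:
        hold = np.array(sorted(fold), dtype=int)
        train_a = np.setdiff1d(by_class[c0], hold)
        train_b = np.setdiff1d(by_class[c1], hold)
        if train_a.size == 0 or train_b.size == 0 or hold.size == 0:
            continue
        sol = _solve(sim, train_a, train_b, tol, max_iter, negatives)
        truth = np.isin(hold, by_class[c1]).astype(int)
        for g, cut in enumerate(grid):
            correct[g] += int(np.sum((sol.f[hold] >= cut).astype(int) == truth))
        total += hold.size
    if total == 0:
        return 0.5
    acc = correct / total
    best = np.flatnonzero(acc == acc.max())
    return float(grid[best[np.argmin(np.abs(grid[best] - 0.5))]])
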