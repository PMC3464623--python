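"""Box-constrained quadratic labeling on a similarity graph.

Given non-negative similarities ``s_ij`` and disjoint seed sets A
(Class Zero) and B (Class One), the model minimizes

    (1/2) * sum_ij s_ij (f_i - f_j)^2  =  f^T L f,    L = D - S,

subject to f_a = 0 (a in A), f_b = 1 (b in B), 0 <= f_i <= 1.  With
non-negative similarities L is positive semi-definite, so the problem is
convex.  Two solution paths are provided: the fixed-point sweep
(:func:`solve_iterative`, the production path) and a direct linear-system
solve of the stationarity conditions (:func:`solve_exact`, the
verification oracle).  The two must agree on connected problems; tests
enforce this.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .preprocess import SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_TOL = 1e-6
DEFAULT_MAX_ITER = 10_000


def _as_matrix(sim) -> np.ndarray:
    if isinstance(sim, SimilarityMatrix):
        return sim.values
    return np.asarray(sim, dtype=float)


def build_laplacian(sim, sym_tol: float = 1e-8) -> np.ndarray:
    """Graph Laplacian ``L = D - S`` with ``d_ii = sum_j s_ij``.

    Rows of L sum to zero; for non-negative S, L is positive
    semi-definite.  Raises if S is asymmetric beyond ``sym_tol``.
    """
    s = _as_matrix(sim)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("similarity must be square")
    asym = np.max(np.abs(s - s.T)) if s.size else 0.0
    if asym > sym_tol:
        raise ValueError(f"similarity asymmetric by {asym:g}")
    return np.diag(s.sum(axis=1)) - s


@dataclass
class LabelProblem:
    """A similarity matrix plus disjoint seed sets A (zero) and B (one).

    ``negatives`` controls how negative similarities are handled:
    ``"error"`` (strict, preserves the convexity guarantee) rejects them,
    ``"clip"`` (permissive) zeroes them with a logged count — needed for
    raw signed correlations and noisy simulated matrices.
    """

    sim: SimilarityMatrix
    set_a: np.ndarray
    set_b: np.ndarray
    negatives: str = "error"
    weights: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n = self.sim.n
        self.set_a = np.unique(np.asarray(self.set_a, dtype=int))
        self.set_b = np.unique(np.asarray(self.set_b, dtype=int))
        if self.set_a.size == 0 or self.set_b.size == 0:
            raise ValueError(
                "both seed sets must be nonempty; without them the model "
                "has only the trivial one-class solution"
            )
        for name, s in (("A", self.set_a), ("B", self.set_b)):
            if s.min() < 0 or s.max() >= n:
                raise ValueError(f"seed set {name} has out-of-range indices")
        if np.intersect1d(self.set_a, self.set_b).size:
            raise ValueError("seed sets A and B must be disjoint")
        w = self.sim.values
        neg = w < 0
        if neg.any():
            if self.negatives == "error":
                raise ValueError(
                    f"{int(neg.sum())} negative similarities; use "
                    "negatives='clip' to zero them"
                )
            if self.negatives != "clip":
                raise ValueError(f"unknown negatives mode {self.negatives!r}")
            logger.info("clipped %d negative similarities to 0", int(neg.sum()))
            w = np.where(neg, 0.0, w)
        self.weights = np.asarray(w, dtype=float)

    @property
    def n(self) -> int:
        return self.sim.n

    @property
    def unlabeled(self) -> np.ndarray:
        mask = np.ones(self.n, dtype=bool)
        mask[self.set_a] = False
        mask[self.set_b] = False
        return np.flatnonzero(mask)


@dataclass
class LabelSolution:
    """Continuous label vector with convergence diagnostics.

    ``objective`` is the quadratic form ``f^T L f`` =
    (1/2) sum_ij s_ij (f_i - f_j)^2 at the returned iterate.
    ``degenerate`` flags unlabeled components unreachable from any seed
    (their labels are the initialization value 0).
    """

    f: np.ndarray
    iterations: int
    converged: bool
    residual: float
    objective: float
    degenerate: bool = False
    objective_history: list[float] | None = None


def _objective(weights: np.ndarray, f: np.ndarray) -> float:
    d = f[:, None] - f[None, :]
    return 0.5 * float(np.sum(weights * d * d))


def solve_iterative(
    problem: LabelProblem,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    track_objective: bool = False,
) -> LabelSolution:
    """Fixed-point solve: repeated similarity-weighted averaging.

    Starts from f = 0 on every unlabeled node (seeds at 0/1) and applies
    the synchronous sweep ``f_i <- sum_j s_ij f_j / sum_j s_ij`` to the
    unlabeled nodes until the max-norm change drops below ``tol``.
    Diagonal entries stay in the row sums (this damps the sweep without
    moving the fixed point).  Unlabeled nodes with zero row sum keep
    their current value — with the zero initialization this is what lets
    seed-disconnected groups ride along as pseudo-clusters.

    The iterates obey a maximum principle (they never leave [0, 1]) and
    the objective is non-increasing along the sweep; no clamping is done.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    w = problem.weights
    n = problem.n
    f = np.zeros(n)
    f[problem.set_b] = 1.0
    rowsum = w.sum(axis=1)
    unl = problem.unlabeled
    active = unl[rowsum[unl] > 0]
    history = [_objective(w, f)] if track_objective else None

    iterations = 0
    residual = 0.0
    converged = active.size == 0
    wa = w[active]
    ra = rowsum[active]
    for iterations in range(1, max_iter + 1):
        new = wa @ f / ra
        residual = float(np.max(np.abs(new - f[active]))) if active.size else 0.0
        f[active] = new
        if history is not None:
            history.append(_objective(w, f))
        if residual < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"fixed-point sweep did not converge in {max_iter} iterations "
            f"(last max change {residual:g})",
            RuntimeWarning,
            stacklevel=2,
        )
    degenerate = bool((rowsum[unl] == 0).any())
    return LabelSolution(
        f=f,
        iterations=iterations,
        converged=converged,
        residual=residual,
        objective=_objective(w, f),
        degenerate=degenerate,
        objective_history=history,
    )


def solve_exact(problem: LabelProblem) -> LabelSolution:
    """Direct solve of the stationarity system on the unlabeled block.

    The interior fixed point is the harmonic solution of
    ``(D_UU - S_UU) f_U = S_UB 1`` for unlabeled index set U.  A singular
    system (unlabeled nodes disconnected from every seed) falls back to
    the minimum-norm least-squares solution, flagged ``degenerate`` —
    which assigns 0 to fully disconnected components, consistent with the
    iterative path's initialization.

    Tiny numerical excursions outside [0, 1] are clamped.
    """
    w = problem.weights
    n = problem.n
    f = np.zeros(n)
    f[problem.set_b] = 1.0
    u = problem.unlabeled
    degenerate = False
    if u.size:
        rowsum = w.sum(axis=1)
        a = np.diag(rowsum[u]) - w[np.ix_(u, u)]
        b = w[np.ix_(u, problem.set_b)].sum(axis=1)
        fu = None
        try:
            cand = np.linalg.solve(a, b)
            ok = np.all(np.isfinite(cand))
            if ok:
                res = np.max(np.abs(a @ cand - b))
                scale = max(1.0, float(np.max(np.abs(b))) if b.size else 1.0)
                ok = res <= 1e-8 * scale
            if ok:
                fu = cand
        except np.linalg.LinAlgError:
            fu = None
        if fu is None:
            fu, *_ = np.linalg.lstsq(a, b, rcond=None)
            degenerate = True
        f[u] = np.clip(fu, 0.0, 1.0)
    return LabelSolution(
        f=f,
        iterations=0,
        converged=True,
        residual=0.0,
        objective=_objective(w, f),
        degenerate=degenerate,
    )


def binarize(solution, cutoff: float = 0.5) -> np.ndarray:
    """Threshold continuous labels into hard 0/1 calls.

    ``f < cutoff`` is Class Zero, ``f > cutoff`` Class One; the tie
    ``f == cutoff`` goes to Class One (documented rule).  ``cutoff`` must
    lie strictly inside (0, 1); it can be learned by cross-validation
    when labeled data are available (see ``prediction.learn_cutoff``),
    0.5 being the natural default.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cutoff must lie strictly between 0 and 1")
    f = solution.f if isinstance(solution, LabelSolution) else np.asarray(solution)
    return (f >= cutoff).astype(int)
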