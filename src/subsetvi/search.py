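"""Best subset selection under force-in/force-out constraints.

Engines
-------
``exhaustive``        enumerate every admissible subset (guard: <= 25 free).
``branch_and_bound``  depth-first search with a likelihood bound; returns
                      exactly the exhaustive answer, usually visiting far
                      fewer nodes.
``forward``           greedy addition from the forced-in set.
``backward``          greedy elimination from the all-included model.

All engines minimize Q(A) = -2*loglik(A) + lambda*|A| and share one
deterministic tie-break: among subsets whose Q values agree within an
absolute tolerance of 1e-9, prefer fewer variables, then the
lexicographically smallest index sequence.

The branch-and-bound bound at a node with fixed-in set F and free set U is

    neg2ll(F ∪ U) + lambda*|F|  <=  Q(A)   for every A with F ⊆ A ⊆ F ∪ U,

since the log-likelihood is monotone in model nesting and every admissible A
pays at least the penalty of F.  A subtree is pruned only when its bound
exceeds the incumbent by more than the tie tolerance, so tie resolution is
identical to exhaustive enumeration.

:class:`SubsetScanner` is the batch engine behind bootstrap-scale work: for
one fixed design it pre-factorizes every subset's normal equations, after
which the residual sums of squares of all 2^p subsets can be evaluated for
hundreds of response vectors at once with a single tensor contraction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import SearchSizeError
from .linear_model import FitResult, GramCache, Penalty, fit_subset, gaussian_neg2ll

__all__ = [
    "TIE_TOL",
    "SearchProblem",
    "SearchResult",
    "exhaustive_search",
    "branch_and_bound_search",
    "heuristic_search",
    "best_subset",
    "SubsetScanner",
    "EXACT_ENGINES",
]

#: Absolute Q tolerance inside which two subsets are considered tied.
TIE_TOL = 1e-9

#: Free-variable limit for exhaustive enumeration.
EXHAUSTIVE_GUARD = 25

EXACT_ENGINES = frozenset({"exhaustive", "branch_and_bound"})


@dataclass(frozen=True)
class SearchProblem:
    """A constrained subset-selection problem over a cached design."""

    gram: GramCache
    penalty: Penalty
    forced_in: frozenset[int] = frozenset()
    forced_out: frozenset[int] = frozenset()
    engine: str = "branch_and_bound"

    def __post_init__(self) -> None:
        fin = frozenset(int(i) for i in self.forced_in)
        fout = frozenset(int(i) for i in self.forced_out)
        if fin & fout:
            raise ValueError(f"forced_in and forced_out overlap: {sorted(fin & fout)}")
        for s in (fin, fout):
            if any(i < 0 or i >= self.gram.p for i in s):
                raise IndexError(f"constraint indices out of range 0..{self.gram.p - 1}")
        object.__setattr__(self, "forced_in", fin)
        object.__setattr__(self, "forced_out", fout)

    @property
    def free(self) -> tuple[int, ...]:
        return tuple(
            i
            for i in range(self.gram.p)
            if i not in self.forced_in and i not in self.forced_out
        )


@dataclass(frozen=True)
class SearchResult:
    active: tuple[int, ...]
    q: float
    fit: FitResult
    nodes_visited: int


def _prefer(q_new: float, a_new: tuple[int, ...], q_old: float, a_old: tuple[int, ...]) -> bool:
    """Deterministic comparator: lower Q, then fewer variables, then lex order."""
    if q_new < q_old - TIE_TOL:
        return True
    if q_new > q_old + TIE_TOL:
        return False
    return (len(a_new), a_new) < (len(a_old), a_old)


def exhaustive_search(problem: SearchProblem) -> SearchResult:
    """Enumerate all admissible subsets and return the minimum-Q one."""
    free = problem.free
    if len(free) > EXHAUSTIVE_GUARD:
        raise SearchSizeError(
            f"{len(free)} free variables exceed the exhaustive guard of "
            f"{EXHAUSTIVE_GUARD}; use the branch_and_bound engine"
        )
    lam = problem.penalty.lam
    base = tuple(sorted(problem.forced_in))
    best_fit = None
    best_q = np.inf
    best_active: tuple[int, ...] = ()
    nodes = 0
    # size-major, lexicographic order makes the tie-break fall out of the scan
    for k in range(len(free) + 1):
        for comb in itertools.combinations(free, k):
            active = tuple(sorted(base + comb))
            fit = fit_subset(problem.gram, active, lam)
            nodes += 1
            if best_fit is None or _prefer(fit.q, active, best_q, best_active):
                best_fit, best_q, best_active = fit, fit.q, active
    assert best_fit is not None
    return SearchResult(best_active, best_q, best_fit, nodes)


def branch_and_bound_search(problem: SearchProblem) -> SearchResult:
    """Exact constrained search; same answer and tie-break as exhaustive."""
    lam = problem.penalty.lam
    gram = problem.gram
    base = tuple(sorted(problem.forced_in))
    free = problem.free
    nodes = 0

    def fit_of(active: Iterable[int]) -> FitResult:
        nonlocal nodes
        nodes += 1
        return fit_subset(gram, active, lam)

    root_fit = fit_of(base)
    if not free:
        return SearchResult(root_fit.active, root_fit.q, root_fit, nodes)

    # branch on the variables with the largest single-variable Q drop first
    drops = []
    for v in free:
        f = fit_of(base + (v,))
        drops.append((root_fit.neg2ll - f.neg2ll, -v, v, f))
    drops.sort(reverse=True)
    order = [d[2] for d in drops]

    # incumbent from a greedy forward pass: a good early bound
    inc = heuristic_search(
        SearchProblem(gram, problem.penalty, problem.forced_in, problem.forced_out, "forward")
    )
    nodes += inc.nodes_visited
    best_fit = inc.fit
    best_q = inc.q
    best_active = inc.active
    if _prefer(root_fit.q, root_fit.active, best_q, best_active):
        best_fit, best_q, best_active = root_fit, root_fit.q, root_fit.active
    for _, _, v, f in drops:
        if _prefer(f.q, f.active, best_q, best_active):
            best_fit, best_q, best_active = f, f.q, f.active

    def descend(fixed: tuple[int, ...], fixed_fit: FitResult, i: int) -> None:
        nonlocal best_fit, best_q, best_active
        if i >= len(order):
            return
        remaining = order[i:]
        relax = fit_of(tuple(sorted(fixed + tuple(remaining))))
        bound = relax.neg2ll + lam * len(fixed)
        if bound > best_q + TIE_TOL:
            return  # no descendant can beat or tie the incumbent
        if _prefer(relax.q, relax.active, best_q, best_active):
            best_fit, best_q, best_active = relax, relax.q, relax.active
        v = order[i]
        child = tuple(sorted(fixed + (v,)))
        child_fit = fit_of(child)
        if _prefer(child_fit.q, child_fit.active, best_q, best_active):
            best_fit, best_q, best_active = child_fit, child_fit.q, child_fit.active
        descend(child, child_fit, i + 1)  # include v first: likelier improvements
        descend(fixed, fixed_fit, i + 1)

    descend(base, root_fit, 0)
    return SearchResult(best_active, best_q, best_fit, nodes)


def heuristic_search(problem: SearchProblem) -> SearchResult:
    """Greedy forward addition or backward elimination.

    Returns a locally optimal subset: no single addition (forward) or
    removal (backward) of a free variable decreases Q.  The result's Q is an
    upper bound on the exact minimum.
    """
    if problem.engine not in ("forward", "backward"):
        raise ValueError(f"heuristic engine must be forward or backward, got {problem.engine!r}")
    lam = problem.penalty.lam
    gram = problem.gram
    nodes = 0

    def fit_of(active):
        nonlocal nodes
        nodes += 1
        return fit_subset(gram, active, lam)

    if problem.engine == "forward":
        current = tuple(sorted(problem.forced_in))
        movable = set(problem.free)
    else:
        current = tuple(sorted(set(problem.forced_in) | set(problem.free)))
        movable = set(problem.free)
    cur_fit = fit_of(current)
    while movable:
        best_move = None
        best_move_fit = None
        for v in sorted(movable):
            if problem.engine == "forward":
                cand = tuple(sorted(current + (v,)))
            else:
                cand = tuple(i for i in current if i != v)
            f = fit_of(cand)
            if best_move_fit is None or _prefer(f.q, f.active, best_move_fit.q, best_move_fit.active):
                best_move, best_move_fit = v, f
        if best_move_fit is not None and best_move_fit.q < cur_fit.q - TIE_TOL:
            current = best_move_fit.active
            cur_fit = best_move_fit
            movable.discard(best_move)
        else:
            break
    return SearchResult(cur_fit.active, cur_fit.q, cur_fit, nodes)


def best_subset(problem: SearchProblem) -> SearchResult:
    """Dispatch on ``problem.engine``."""
    if problem.engine == "exhaustive":
        return exhaustive_search(problem)
    if problem.engine == "branch_and_bound":
        return branch_and_bound_search(problem)
    return heuristic_search(problem)


class SubsetScanner:
    """All-subsets least squares for one fixed design, batched over responses.

    For every subset S of the p candidate columns the scanner stores the
    inverse normal-equations matrix of ``[1, X_S]`` embedded in the full
    (p+1) x (p+1) frame.  For a response batch ``Y`` (n x B) the residual sum
    of squares of every subset and every response is then

        rss[S, b] = y_b'y_b - c_b' P_S c_b,      c_b = [1, X]' y_b,

    one ``einsum`` over a (2^p, p+1, p+1) tensor.  Memory and setup grow as
    2^p, so the scanner is intended for p up to ~15; exact searches cover
    larger problems one response at a time.
    """

    def __init__(self, X: np.ndarray, max_p: int = 15):
        X = np.asarray(X, dtype=float)
        n, p = X.shape
        if p > max_p:
            raise SearchSizeError(f"scanner supports up to {max_p} columns, got {p}")
        self.n, self.p = n, p
        self.Z = np.column_stack([np.ones(n), X])
        G = self.Z.T @ self.Z
        nsub = 1 << p
        self.subsets: list[tuple[int, ...]] = []
        self.sizes = np.empty(nsub, dtype=int)
        self.membership = np.zeros((nsub, p), dtype=bool)
        self.P = np.zeros((nsub, p + 1, p + 1))
        for code in range(nsub):
            active = tuple(i for i in range(p) if code >> i & 1)
            idx = np.array((0,) + tuple(a + 1 for a in active))
            self.P[code][np.ix_(idx, idx)] = np.linalg.inv(G[np.ix_(idx, idx)])
            self.subsets.append(active)
            self.sizes[code] = len(active)
            self.membership[code, list(active)] = True

    def rss(self, Y: np.ndarray) -> np.ndarray:
        """Residual sums of squares, shape (2^p, B), for responses Y (n, B)."""
        Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T  # (n, B)
        C = self.Z.T @ Y  # (p+1, B)
        yty = np.einsum("ib,ib->b", Y, Y)
        return yty[None, :] - np.einsum("sij,ib,jb->sb", self.P, C, C)

    def neg2ll(self, Y: np.ndarray) -> np.ndarray:
        return gaussian_neg2ll(self.rss(Y), self.n)

    def mvi_batch(
        self,
        Y: np.ndarray,
        group: Sequence[int],
        lams: Sequence[float],
    ) -> np.ndarray:
        """Modified importance of ``group`` for each response and each lambda.

        Returns shape (len(lams), B).  The two constrained minima are taken
        over subsets containing every group member ("included") and subsets
        containing none of them ("excluded"); subsets with partial membership
        belong to neither branch and never enter either minimum.
        """
        group = tuple(sorted(set(int(g) for g in group)))
        neg2 = self.neg2ll(Y)  # (2^p, B)
        inc = self.membership[:, group].all(axis=1)
        exc = ~self.membership[:, group].any(axis=1)
        # collapse each branch to per-size neg2ll minima: the penalized
        # minimum for any lambda is then a min over at most p+1 numbers
        out = np.empty((len(lams), neg2.shape[1]))
        mins = {}
        for label, mask in (("inc", inc), ("exc", exc)):
            sizes = self.sizes[mask]
            vals = neg2[mask]
            ks = np.unique(sizes)
            m = np.stack([vals[sizes == k].min(axis=0) for k in ks])
            mins[label] = (ks, m)
        ks_i, m_i = mins["inc"]
        ks_e, m_e = mins["exc"]
        for j, lam in enumerate(lams):
            q_inc = (m_i + lam * ks_i[:, None]).min(axis=0)
            q_exc = (m_e + lam * ks_e[:, None]).min(axis=0)
            out[j] = q_exc - q_inc + lam * len(group)
        return out
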