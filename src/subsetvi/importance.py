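"""Variable-importance measures for best subset selection.

For a variable set S with index set ``members`` the importance under penalty
``lambda`` is the gap between the two constrained penalized-likelihood
optima:

    VI(S) = min_{A : S ∩ A = ∅} Q(A)  -  min_{A : S ⊆ A} Q(A),

i.e. the best attainable score without the set minus the best attainable
score with the whole set included.  VI is positive exactly when the set
belongs to the globally selected model, negative when it does not, and is
bounded below by ``-lambda*|S|`` (a nesting argument: adding S to the
without-S optimum costs at most its penalty).  The modified measure

    mVI(S) = VI(S) + lambda*|S|

is therefore non-negative and serves as the test statistic for inference.

For a multi-variable set, "included" means every member is active — the
grouped-variable use case is a categorical predictor encoded by several
indicator columns, which enter or leave a model together.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConsistencyError
from .linear_model import Dataset, GramCache, Penalty, penalty_value, wald_squared
from .search import (
    EXACT_ENGINES,
    TIE_TOL,
    SearchProblem,
    SearchResult,
    _prefer,
    best_subset,
)

__all__ = [
    "VariableGroup",
    "ImportanceRecord",
    "variable_importance",
    "modified_importance",
    "importance_table",
    "singleton_groups",
]


@dataclass(frozen=True)
class VariableGroup:
    """A named, non-empty set of predictor column indices tested as one unit."""

    name: str
    members: tuple[int, ...]

    def __post_init__(self) -> None:
        members = tuple(sorted(set(int(m) for m in self.members)))
        if not members:
            raise ValueError(f"group {self.name!r} is empty")
        object.__setattr__(self, "members", members)

    @property
    def size(self) -> int:
        return len(self.members)


def singleton_groups(dataset: Dataset) -> list[VariableGroup]:
    """The default grouping: one group per predictor column."""
    return [VariableGroup(name, (j,)) for j, name in enumerate(dataset.names)]


@dataclass(frozen=True)
class ImportanceRecord:
    group: VariableGroup
    penalty: Penalty
    vi: float
    mvi: float
    selected: bool
    q_excluded: float
    q_included: float
    exact: bool
    search_excluded: SearchResult
    search_included: SearchResult


def variable_importance(problem: SearchProblem, group: VariableGroup) -> ImportanceRecord:
    """VI and mVI of ``group`` via two constrained subset searches.

    ``q_excluded`` is the minimum Q with every member forced out;
    ``q_included`` the minimum with every member forced in.  The ``selected``
    flag reports whether the group sits inside the unconstrained optimum,
    which for the exact engines coincides with ``vi > 0`` (a Q tie at vi = 0
    resolves to the smaller model, which excludes the group).

    A heuristic engine is permitted but its record is flagged ``exact=False``
    and the mVI >= 0 / VI >= -lambda|S| bounds are no longer guaranteed.
    """
    members = set(group.members)
    if members & problem.forced_in or members & problem.forced_out:
        raise ValueError(
            f"group {group.name!r} overlaps the problem's forced_in/forced_out sets"
        )
    excluded = best_subset(
        replace(problem, forced_out=frozenset(problem.forced_out | members))
    )
    included = best_subset(
        replace(problem, forced_in=frozenset(problem.forced_in | members))
    )
    lam = problem.penalty.lam
    vi = excluded.q - included.q
    exact = problem.engine in EXACT_ENGINES
    if not exact:
        selected = vi > 0
    elif group.size == 1:
        # the two branches partition the model space for singletons, so the
        # unconstrained optimum is whichever branch optimum the search
        # comparator prefers; a Q tie resolves by size then index order
        if abs(vi) <= TIE_TOL:
            selected = _prefer(included.q, included.active, excluded.q, excluded.active)
        else:
            selected = vi > 0
    else:
        # subsets holding part of the group sit in neither branch, so the
        # flag needs the genuinely unconstrained optimum
        unconstrained = best_subset(problem)
        selected = members <= set(unconstrained.active)
    return ImportanceRecord(
        group=group,
        penalty=problem.penalty,
        vi=vi,
        mvi=vi + lam * group.size,
        selected=selected,
        q_excluded=excluded.q,
        q_included=included.q,
        exact=exact,
        search_excluded=excluded,
        search_included=included,
    )


def modified_importance(record: ImportanceRecord, penalty: Penalty) -> float:
    """mVI = VI + lambda*|S|; non-negative whenever the searches were exact."""
    if abs(record.penalty.lam - penalty.lam) > 1e-12:
        raise ConsistencyError(
            f"record was computed with lambda={record.penalty.lam:g}, "
            f"not lambda={penalty.lam:g}"
        )
    return record.vi + penalty.lam * record.group.size


def importance_table(
    dataset: Dataset,
    grouping: Sequence[VariableGroup] | None = None,
    criteria: Sequence[str] = ("AIC", "HQIC", "BIC"),
    engine: str = "branch_and_bound",
    statistic: str = "mvi",
) -> pd.DataFrame:
    """Importance of every group under every criterion, plus the full model.

    The ``Full`` column holds the squared Wald statistic of each group in the
    full model — the conventional importance yardstick the subset-selection
    measures are compared against.  Criterion columns hold mVI by default
    (``statistic="vi"`` switches to the signed measure; ``"both"`` returns a
    long-format frame with vi, mvi and the selection flag).
    """
    if grouping is None:
        grouping = singleton_groups(dataset)
    gram = GramCache.from_dataset(dataset)
    records: dict[str, dict[str, ImportanceRecord]] = {}
    for crit in criteria:
        pen = penalty_value(crit, dataset.n)
        problem = SearchProblem(gram, pen, engine=engine)
        records[crit] = {g.name: variable_importance(problem, g) for g in grouping}
    full = {g.name: wald_squared(dataset, g.members) for g in grouping}
    if statistic == "both":
        rows = []
        for crit in criteria:
            for g in grouping:
                r = records[crit][g.name]
                rows.append(
                    {
                        "group": g.name,
                        "criterion": crit,
                        "vi": r.vi,
                        "mvi": r.mvi,
                        "selected": r.selected,
                        "wald_full": full[g.name],
                    }
                )
        return pd.DataFrame(rows)
    if statistic not in ("vi", "mvi"):
        raise ValueError("statistic must be 'vi', 'mvi' or 'both'")
    data = {"Full": [full[g.name] for g in grouping]}
    for crit in criteria:
        data[crit] = [
            getattr(records[crit][g.name], statistic) for g in grouping
        ]
    return pd.DataFrame(data, index=[g.name for g in grouping])
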