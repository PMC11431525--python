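"""p-values for the modified variable-importance statistic.

Two reference distributions are offered for mVI:

* a naive chi-square with |S| degrees of freedom, adequate when predictors
  are close to independent but anti-conservative under strong correlation,
  increasingly so as the penalty grows with n (BIC, HQIC);
* a parametric bootstrap of the null: the Gaussian model containing every
  predictor EXCEPT the set under test is fitted, new responses are drawn
  from it with the design matrix held fixed (preserving the correlation
  structure among predictors), and mVI is recomputed on each draw.  The
  p-value is the add-one tail fraction (1 + #{draws >= observed}) / (B + 1),
  which is a valid p-value at any finite number of replicates B.

Each bootstrap replicate requires two constrained best-subset searches, so a
full table over p variables costs 2*p*B searches; the batched all-subsets
scanner makes this affordable by sharing one factorization of the design
across every replicate and every variable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SubsetVIError
from .importance import ImportanceRecord, VariableGroup, singleton_groups, variable_importance
from .linear_model import (
    Dataset,
    GramCache,
    Penalty,
    fit_subset,
    penalty_value,
    wald_pvalue,
)
from .search import EXACT_ENGINES, SearchProblem, SubsetScanner, best_subset

__all__ = [
    "BootstrapSettings",
    "PValueRecord",
    "chisq_pvalue",
    "bootstrap_null_sample",
    "bootstrap_pvalue",
    "group_pvalue",
    "pvalue_table",
]

#: Exact-engine mVI values this far below zero indicate a real defect rather
#: than roundoff.
_NEG_TOL = 1e-6


@dataclass
class BootstrapSettings:
    """Replication settings for the parametric bootstrap.

    ``seed`` feeds a per-group substream derived deterministically from
    (seed, group index), so tables are reproducible and groups are
    independent of each other's draw order.  ``variance`` selects the noise
    scale of the generator: the profile-likelihood MLE rss/n (default,
    coherent with the fitting criterion) or the unbiased rss/(n-k-1).
    ``searches_performed`` counts the constrained subset searches the
    replicates implied (two per replicate per group), whichever execution
    path carried them out.
    """

    nboot: int = 100
    seed: int = 0
    engine: str = "branch_and_bound"
    variance: str = "mle"
    scanner_max_p: int = 15
    searches_performed: int = 0

    def __post_init__(self) -> None:
        if self.nboot < 1:
            raise ValueError("nboot must be at least 1")
        if self.variance not in ("mle", "unbiased"):
            raise ValueError("variance must be 'mle' or 'unbiased'")


@dataclass(frozen=True)
class PValueRecord:
    group: VariableGroup
    penalty: Penalty
    mvi_obs: float
    null_draws: np.ndarray
    p: float
    method: str


def chisq_pvalue(mvi_obs: float, df: int) -> float:
    """Upper-tail chi-square probability of the observed mVI with df = |S|."""
    if df < 1:
        raise ValueError("degrees of freedom must be at least 1")
    if mvi_obs < -_NEG_TOL:
        raise SubsetVIError(
            f"negative mVI {mvi_obs:g}: the statistic is non-negative under "
            "exact search engines; a heuristic engine likely produced this"
        )
    return float(stats.chi2.sf(max(mvi_obs, 0.0), df))


def bootstrap_pvalue(mvi_obs: float, draws: np.ndarray) -> float:
    """Add-one tail estimator (1 + #{draws >= observed}) / (B + 1)."""
    draws = np.asarray(draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one null draw")
    return float((1 + np.count_nonzero(draws >= mvi_obs)) / (draws.size + 1))


def _group_rng(settings: BootstrapSettings, group_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([settings.seed, group_index]))


def _null_generator(dataset: Dataset, group: VariableGroup, settings: BootstrapSettings):
    """Fitted mean and noise SD of the model omitting the group's columns."""
    reduced = tuple(j for j in range(dataset.p) if j not in group.members)
    gram = GramCache.from_dataset(dataset)
    fit = fit_subset(gram, reduced, 0.0)
    Z = np.column_stack([np.ones(dataset.n), dataset.X[:, reduced]])
    mu = Z @ fit.coefficients
    if settings.variance == "mle":
        sigma2 = fit.rss / dataset.n
    else:
        sigma2 = fit.rss / (dataset.n - len(reduced) - 1)
    return mu, math.sqrt(sigma2)


def bootstrap_null_sample(
    dataset: Dataset,
    group: VariableGroup,
    penalty: Penalty,
    settings: BootstrapSettings,
    group_index: int = 0,
    scanner: SubsetScanner | None = None,
) -> np.ndarray:
    """Draw B null mVI values for ``group`` by the parametric bootstrap.

    The response is regenerated from the fitted reduced model (all columns
    except the group) with X held fixed, and the group's mVI recomputed on
    each draw.  Exact engines guarantee every draw is non-negative.
    """
    rng = _group_rng(settings, group_index)
    mu, sigma = _null_generator(dataset, group, settings)
    B = settings.nboot
    exact = settings.engine in EXACT_ENGINES
    if exact and scanner is None and dataset.p <= settings.scanner_max_p:
        scanner = SubsetScanner(dataset.X, max_p=settings.scanner_max_p)
    if exact and scanner is not None:
        # replicate-major draw order keeps the stream identical to the
        # one-search-at-a-time path below
        Y = mu[:, None] + sigma * rng.standard_normal((B, dataset.n)).T
        draws = scanner.mvi_batch(Y, group.members, [penalty.lam])[0]
    else:
        gram = GramCache.from_dataset(dataset)
        draws = np.empty(B)
        members = frozenset(group.members)
        for b in range(B):
            gram.refresh_y(dataset.X, mu + sigma * rng.standard_normal(dataset.n))
            excluded = best_subset(
                SearchProblem(gram, penalty, forced_out=members, engine=settings.engine)
            )
            included = best_subset(
                SearchProblem(gram, penalty, forced_in=members, engine=settings.engine)
            )
            draws[b] = excluded.q - included.q + penalty.lam * group.size
    settings.searches_performed += 2 * B
    if exact:
        low = draws.min()
        if low < -_NEG_TOL:
            raise SubsetVIError(f"exact-engine null draw went negative ({low:g})")
        draws = np.maximum(draws, 0.0)
    return draws


def group_pvalue(
    dataset: Dataset,
    group: VariableGroup,
    penalty: Penalty,
    settings: BootstrapSettings,
    method: str = "bootstrap",
    group_index: int = 0,
    scanner: SubsetScanner | None = None,
    record: ImportanceRecord | None = None,
) -> PValueRecord:
    """p-value for one variable set under one penalty."""
    if record is None:
        gram = GramCache.from_dataset(dataset)
        engine = settings.engine if settings.engine in EXACT_ENGINES else "branch_and_bound"
        record = variable_importance(SearchProblem(gram, penalty, engine=engine), group)
    mvi_obs = record.mvi
    if method == "chisq":
        return PValueRecord(
            group, penalty, mvi_obs, np.empty(0), chisq_pvalue(mvi_obs, group.size), "chisq"
        )
    if method != "bootstrap":
        raise ValueError("method must be 'bootstrap' or 'chisq'")
    draws = bootstrap_null_sample(dataset, group, penalty, settings, group_index, scanner)
    return PValueRecord(group, penalty, mvi_obs, draws, bootstrap_pvalue(mvi_obs, draws), "bootstrap")


def _selected_model_wald_p(dataset: Dataset, active: tuple[int, ...], group: VariableGroup) -> float:
    """Wald p-value for the group inside the selected model, NaN if excluded.

    These are the conventional post-selection p-values; they ignore the
    selection event and are reported for comparison, not as valid tests.
    """
    if not set(group.members) <= set(active):
        return float("nan")
    sub = Dataset(
        y=dataset.y,
        X=dataset.X[:, list(active)],
        names=tuple(dataset.names[j] for j in active),
    )
    pos = tuple(active.index(j) for j in group.members)
    return wald_pvalue(sub, pos)


def pvalue_table(
    dataset: Dataset,
    grouping: Sequence[VariableGroup] | None = None,
    criteria: Sequence[str] = ("AIC", "HQIC", "BIC"),
    settings: BootstrapSettings | None = None,
    method: str = "bootstrap",
) -> pd.DataFrame:
    """p-values per group: full-model Wald, per-criterion mVI, selected Wald.

    Layout: a ``Full`` column of full-model Wald p-values, then for each
    criterion the mVI-based p-value (bootstrap by default) and the Wald
    p-value from that criterion's selected model, blank (NaN) for variables
    the selected model excludes.
    """
    if grouping is None:
        grouping = singleton_groups(dataset)
    if settings is None:
        settings = BootstrapSettings()
    gram = GramCache.from_dataset(dataset)
    scanner = None
    if method == "bootstrap" and settings.engine in EXACT_ENGINES and dataset.p <= settings.scanner_max_p:
        scanner = SubsetScanner(dataset.X, max_p=settings.scanner_max_p)
    out: dict[str, list[float]] = {"Full": [wald_pvalue(dataset, g.members) for g in grouping]}
    for crit in criteria:
        pen = penalty_value(crit, dataset.n)
        problem = SearchProblem(gram, pen, engine="branch_and_bound")
        selected = best_subset(problem).active
        pcol, wcol = [], []
        for gi, g in enumerate(grouping):
            rec = variable_importance(problem, g)
            pv = group_pvalue(
                dataset, g, pen, settings, method, group_index=gi, scanner=scanner, record=rec
            )
            pcol.append(pv.p)
            wcol.append(_selected_model_wald_p(dataset, selected, g))
        out[crit] = pcol
        out[f"{crit} (Wald)"] = wcol
    return pd.DataFrame(out, index=[g.name for g in grouping])
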