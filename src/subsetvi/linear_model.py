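"""Gaussian linear-model fitting primitives for penalized subset selection.

The score being minimized over candidate models is

    Q(beta | X, y, lambda) = -2 * loglik(beta | X, y) + lambda * ||beta||_0,

where ``||beta||_0`` counts the non-zero slope coefficients (the intercept is
always included and never counted) and ``lambda`` is the per-parameter
penalty of an information criterion: 2 for AIC, log(n) for BIC and
2*log(log(n)) for HQIC.

The Gaussian -2 log-likelihood is profiled over the error variance, so for an
active set ``A`` with residual sum of squares ``rss``

    -2 * loglik = n * (log(2*pi*rss/n) + 1),

with the variance MLE ``rss/n`` plugged in.  All constants are kept, so the
printed Q values are well defined; only Q differences matter for importance
measures.

Subset refits are driven by a cached cross-product (Gram) matrix of the
column block ``[1, X, y]``: once the cache is built, the cost of fitting any
subset no longer depends on the number of observations, which is what makes
bootstrap-scale repeated subset searches affordable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exceptions import (
    DegenerateFitError,
    InvalidPenaltyError,
    RankDeficiencyError,
    ZeroVarianceError,
)

__all__ = [
    "Dataset",
    "Penalty",
    "GramCache",
    "FitResult",
    "penalty_value",
    "fit_subset",
    "wald_squared",
    "wald_pvalue",
    "standardize_predictors",
    "raw_coefficients",
]

#: Relative Cholesky pivot below which a subsystem is declared singular.
PIVOT_RTOL = 1e-10

LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class Dataset:
    """An outcome vector and a matrix of candidate predictors.

    Parameters
    ----------
    y : (n,) array of the outcome.
    X : (n, p) array of candidate predictors.
    names : p unique column labels.
    standardized : whether predictors are centered/scaled to unit SD.
    center, scale : original column locations/scales when standardized,
        kept so raw-scale coefficients remain recoverable.
    """

    y: np.ndarray
    X: np.ndarray
    names: tuple[str, ...]
    standardized: bool = False
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.X, dtype=float)
        if y.ndim != 1:
            raise ValueError("y must be one-dimensional")
        if X.ndim != 2:
            raise ValueError("X must be two-dimensional")
        if X.shape[0] != y.shape[0]:
            raise ValueError(
                f"X has {X.shape[0]} rows but y has {y.shape[0]} entries"
            )
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValueError("missing or non-finite values are not allowed")
        names = tuple(str(c) for c in self.names)
        if len(names) != X.shape[1]:
            raise ValueError("need one label per predictor column")
        if len(set(names)) != len(names):
            raise ValueError("column labels must be unique")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"no predictor column named {label!r}") from None


@dataclass(frozen=True)
class Penalty:
    """A per-parameter penalty ``lambda`` and the criterion that produced it."""

    criterion: str
    lam: float

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise InvalidPenaltyError("penalty lambda must be non-negative")


def penalty_value(criterion: str, n: int | None = None, lam: float | None = None) -> Penalty:
    """Return the penalty for an information criterion at sample size ``n``.

    AIC uses lambda = 2; BIC uses lambda = log(n); HQIC uses
    lambda = 2*log(log(n)) (the Hannan-Quinn constant k fixed at 1, so the
    penalty is positive only for n >= 3, which is required).  ``custom``
    passes a user lambda through unchanged.
    """
    crit = criterion.strip().lower()
    if crit == "aic":
        return Penalty("AIC", 2.0)
    if crit == "bic":
        if n is None or n < 1:
            raise InvalidPenaltyError("BIC requires a sample size n >= 1")
        return Penalty("BIC", math.log(n))
    if crit == "hqic":
        if n is None or n < 3:
            raise InvalidPenaltyError(
                "HQIC requires n >= 3 (log log n is non-positive or undefined below)"
            )
        return Penalty("HQIC", 2.0 * math.log(math.log(n)))
    if crit == "custom":
        if lam is None or lam < 0:
            raise InvalidPenaltyError("custom criterion needs lambda >= 0")
        return Penalty("custom", float(lam))
    raise InvalidPenaltyError(f"unknown criterion {criterion!r}")


class GramCache:
    """Cross-product matrix of the block ``[1, X, y]``.

    Row/column layout: index 0 is the intercept column of ones, indices
    ``1..p`` are predictors, index ``p+1`` is the outcome.  ``refresh_y``
    replaces only the last row/column (X'y and y'y), which is the cheap
    update exploited when the bootstrap regenerates the response while the
    design is held fixed.
    """

    __slots__ = ("G", "n", "p")

    def __init__(self, G: np.ndarray, n: int):
        G = np.asarray(G, dtype=float)
        if G.ndim != 2 or G.shape[0] != G.shape[1]:
            raise ValueError("Gram matrix must be square")
        self.G = G
        self.n = int(n)
        self.p = G.shape[0] - 2

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "GramCache":
        return cls.from_arrays(dataset.X, dataset.y)

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: np.ndarray) -> "GramCache":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = X.shape[0]
        block = np.empty((n, X.shape[1] + 2))
        block[:, 0] = 1.0
        block[:, 1:-1] = X
        block[:, -1] = y
        return cls(block.T @ block, n)

    def refresh_y(self, X: np.ndarray, y: np.ndarray) -> None:
        """Update the cache in place for a new response on the same design."""
        y = np.asarray(y, dtype=float)
        if y.shape[0] != self.n:
            raise ValueError("replacement response has the wrong length")
        self.G[-1, 0] = self.G[0, -1] = y.sum()
        xty = X.T @ y
        self.G[-1, 1:-1] = xty
        self.G[1:-1, -1] = xty
        self.G[-1, -1] = y @ y

    @property
    def yty(self) -> float:
        return float(self.G[-1, -1])


@dataclass(frozen=True)
class FitResult:
    """A least-squares fit of the intercept plus an active predictor set."""

    active: tuple[int, ...]
    coefficients: np.ndarray  # intercept first, then one slope per active index
    rss: float
    neg2ll: float
    q: float
    lam: float

    @property
    def size(self) -> int:
        """Number of active slopes; the intercept is not counted."""
        return len(self.active)


def _cholesky_solve(M: np.ndarray, b: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    """Solve M theta = b by Cholesky with a relative pivot guard.

    A pivot smaller than ``PIVOT_RTOL`` times the corresponding diagonal entry
    means the subsystem is rank deficient; the error names the first column
    at which elimination breaks down.
    """
    try:
        L = np.linalg.cholesky(M)
    except np.linalg.LinAlgError:
        L = None
    if L is not None:
        piv = np.diagonal(L) ** 2
        bad = piv < PIVOT_RTOL * np.abs(np.diagonal(M))
        if not np.any(bad):
            z = np.linalg.solve(L, b)  # triangular, but small systems
            return np.linalg.solve(L.T, z)
        j = int(np.argmax(bad))
    else:
        # diagnose the first failing pivot with a manual factorization
        k = M.shape[0]
        Lm = np.zeros_like(M)
        j = k - 1
        for i in range(k):
            s = M[i, i] - Lm[i, :i] @ Lm[i, :i]
            if s <= PIVOT_RTOL * abs(M[i, i]):
                j = i
                break
            Lm[i, i] = math.sqrt(s)
            Lm[i + 1 :, i] = (M[i + 1 :, i] - Lm[i + 1 :, :i] @ Lm[i, :i]) / Lm[i, i]
    raise RankDeficiencyError(
        f"normal equations singular at column {labels[j]!r} "
        f"(pivot below {PIVOT_RTOL:g} of its diagonal)"
    )


def gaussian_neg2ll(rss: float | np.ndarray, n: int) -> float | np.ndarray:
    """-2 log-likelihood at the MLE with the profiled variance rss/n."""
    return n * (np.log(2.0 * np.pi * np.asarray(rss) / n) + 1.0)


def fit_subset(gram: GramCache, active: Iterable[int], lam: float) -> FitResult:
    """Least-squares fit of the intercept plus the ``active`` predictors.

    Works entirely from the Gram cache, so the cost is O(|active|^3)
    regardless of the number of observations.
    """
    active = tuple(sorted(int(a) for a in set(active)))
    if active and (active[0] < 0 or active[-1] >= gram.p):
        raise IndexError(f"active indices out of range 0..{gram.p - 1}: {active}")
    idx = np.array((0,) + tuple(a + 1 for a in active), dtype=int)
    M = gram.G[np.ix_(idx, idx)]
    b = gram.G[idx, -1]
    labels = ["(Intercept)"] + [f"x{a}" for a in active]
    theta = _cholesky_solve(M, b, labels)
    rss = float(gram.yty - b @ theta)
    # relative guard: an rss this far below y'y is a numerically perfect fit
    if rss <= 1e-12 * max(gram.yty, 1.0):
        raise DegenerateFitError(
            f"residual sum of squares {rss:g} is numerically zero; "
            "the model fits perfectly and the profile likelihood diverges"
        )
    n = gram.n
    neg2ll = float(gaussian_neg2ll(rss, n))
    return FitResult(
        active=active,
        coefficients=theta,
        rss=rss,
        neg2ll=neg2ll,
        q=neg2ll + lam * len(active),
        lam=float(lam),
    )


def _full_ols(dataset: Dataset):
    """Dense full-model OLS: coefficients, rss and the unscaled covariance."""
    n, p = dataset.n, dataset.p
    if n <= p + 1:
        raise ValueError(f"full model needs n > p + 1 (n={n}, p={p})")
    Z = np.column_stack([np.ones(n), dataset.X])
    M = Z.T @ Z
    labels = ["(Intercept)"] + list(dataset.names)
    beta = _cholesky_solve(M, Z.T @ dataset.y, labels)
    resid = dataset.y - Z @ beta
    rss = float(resid @ resid)
    Minv = np.linalg.inv(M)
    return beta, rss, Minv


def wald_squared(dataset: Dataset, group: Iterable[int]) -> float:
    """Squared Wald statistic for the ``group`` coefficients in the full model.

    For a single variable this is the squared t statistic with the unbiased
    variance estimate rss/(n - p - 1); for a set it is the quadratic-form
    Wald chi-square for the coefficients being jointly zero.
    """
    group = tuple(sorted(int(g) for g in set(group)))
    if not group:
        raise ValueError("group must be non-empty")
    beta, rss, Minv = _full_ols(dataset)
    n, p = dataset.n, dataset.p
    sigma2 = rss / (n - p - 1)
    idx = np.array([g + 1 for g in group])
    bg = beta[idx]
    cov = sigma2 * Minv[np.ix_(idx, idx)]
    if len(group) == 1:
        return float(bg[0] ** 2 / cov[0, 0])
    return float(bg @ np.linalg.solve(cov, bg))


def wald_pvalue(dataset: Dataset, group: Iterable[int]) -> float:
    """Two-sided p-value for the full-model Wald test of the group.

    Singletons use the t reference with n - p - 1 degrees of freedom; sets
    use the chi-square reference with |group| degrees of freedom.
    """
    group = tuple(sorted(set(int(g) for g in group)))
    w = wald_squared(dataset, group)
    if len(group) == 1:
        df = dataset.n - dataset.p - 1
        return float(2.0 * stats.t.sf(math.sqrt(w), df))
    return float(stats.chi2.sf(w, len(group)))


def standardize_predictors(dataset: Dataset) -> Dataset:
    """Center each predictor and scale it to unit sample SD (n-1 denominator).

    The outcome is untouched.  Because every subset's fitted values are
    unchanged by affine transformations of the predictors, selection results
    (active sets, VI, mVI, Q differences) are identical before and after.
    Idempotent on already-standardized data.
    """
    X = dataset.X
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        raise ZeroVarianceError(
            f"constant predictor column {dataset.names[bad[0]]!r} cannot be standardized"
        )
    prev_center = dataset.center if dataset.center is not None else np.zeros(dataset.p)
    prev_scale = dataset.scale if dataset.scale is not None else np.ones(dataset.p)
    return Dataset(
        y=dataset.y,
        X=(X - center) / scale,
        names=dataset.names,
        standardized=True,
        center=prev_center + center * prev_scale,
        scale=prev_scale * scale,
    )


def raw_coefficients(dataset: Dataset, fit: FitResult) -> np.ndarray:
    """Map a fit on standardized predictors back to raw-scale coefficients."""
    if not dataset.standardized or dataset.scale is None:
        return fit.coefficients.copy()
    coefs = fit.coefficients.copy()
    idx = np.array(fit.active, dtype=int)
    if idx.size:
        raw_slopes = coefs[1:] / dataset.scale[idx]
        coefs[0] -= float(raw_slopes @ dataset.center[idx])
        coefs[1:] = raw_slopes
    return coefs
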