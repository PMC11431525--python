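"""Synthetic study design for validating mVI-based p-values.

The generator emulates a six-covariate Gaussian linear model:

* base coefficient vector beta = (2, 3, 4, 5, 6, 7), of which three entries,
  chosen uniformly at random per replicate, are set to zero — these are the
  true nulls whose p-values drive the type-1 error estimates, and the
  relative importance of the retained effects varies across replicates;
* covariate rows x_i ~ N_6(1, Sigma) with the equicorrelation matrix
  Sigma = rho*J + (1-rho)*I, so every pair of predictors has correlation rho;
* outcome y_i ~ N(x_i' beta + 1, sigma^2) with sigma^2 = beta' Sigma beta / SNR.

The signal-to-noise ratio SNR = Var(x'beta)/sigma^2 is tied to the
population coefficient of determination by R^2 = SNR/(1+SNR); the default
SNR of 3/7 (about 0.4286) corresponds to R^2 = 0.3, a deliberately noisy
regime.  sigma^2 is computed from the post-zeroing beta — the coefficients
of the model that actually generates the data — so the realized SNR matches
the target in every replicate; a flag restores the pre-zeroing convention.

Two experiments are built on the generator: pooling the null mVI draws to
compare their distribution with chi-square(1), and converting null p-values
(naive chi-square or parametric bootstrap) into empirical type-1 error
rates at a grid of significance levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .linear_model import Dataset, GramCache, fit_subset, penalty_value
from .search import SubsetScanner

__all__ = [
    "SimDesign",
    "SimulatedDataset",
    "SimResult",
    "equicorrelation_matrix",
    "sigma2_from_snr",
    "simulate_dataset",
    "null_mvi_distribution",
    "type1_error_rates",
]


def equicorrelation_matrix(p: int, rho: float) -> np.ndarray:
    """rho*J_p + (1-rho)*I_p; positive definite for -1/(p-1) < rho < 1."""
    if not (-1.0 / (p - 1) < rho < 1.0):
        raise ValueError(
            f"rho={rho} makes the equicorrelation matrix indefinite for p={p} "
            f"(need -1/{p - 1} < rho < 1)"
        )
    return rho * np.ones((p, p)) + (1.0 - rho) * np.eye(p)


def sigma2_from_snr(beta: np.ndarray, Sigma: np.ndarray, snr: float) -> float:
    """Noise variance giving the target signal-to-noise ratio.

    sigma^2 = beta' Sigma beta / SNR, with SNR = Var(x'beta)/sigma^2; the
    implied population R^2 is SNR/(1+SNR).
    """
    if snr <= 0:
        raise ValueError("signal-to-noise ratio must be positive")
    beta = np.asarray(beta, dtype=float)
    return float(beta @ Sigma @ beta) / snr


@dataclass(frozen=True)
class SimDesign:
    """Parameters of the data-generating process."""

    beta_base: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    n_null: int = 3
    rho: float = 0.0
    snr: float = 3.0 / 7.0
    n: int = 1000
    intercept: float = 1.0
    sigma2_from: str = "post"  # post-zeroing beta (generating model) or "pre"

    def __post_init__(self) -> None:
        if not 0 <= self.n_null <= self.p:
            raise ValueError("n_null must lie in 0..p")
        if self.sigma2_from not in ("post", "pre"):
            raise ValueError("sigma2_from must be 'post' or 'pre'")
        equicorrelation_matrix(self.p, self.rho)  # validates rho

    @property
    def p(self) -> int:
        return len(self.beta_base)

    @property
    def sigma(self) -> np.ndarray:
        return equicorrelation_matrix(self.p, self.rho)


@dataclass(frozen=True)
class SimulatedDataset:
    dataset: Dataset
    null_indices: tuple[int, ...]
    beta: np.ndarray
    sigma2: float


def simulate_dataset(design: SimDesign, seed_or_rng) -> SimulatedDataset:
    """One replicate of the design, fully reproducible from the seed."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator
    ) else seed_or_rng
    p = design.p
    nulls = tuple(sorted(rng.choice(p, size=design.n_null, replace=False).tolist()))
    beta = np.asarray(design.beta_base, dtype=float).copy()
    beta[list(nulls)] = 0.0
    Sigma = design.sigma
    which = beta if design.sigma2_from == "post" else np.asarray(design.beta_base, float)
    sigma2 = sigma2_from_snr(which, Sigma, design.snr)
    L = np.linalg.cholesky(Sigma)
    X = 1.0 + rng.standard_normal((design.n, p)) @ L.T
    y = X @ beta + design.intercept + math.sqrt(sigma2) * rng.standard_normal(design.n)
    dataset = Dataset(y=y, X=X, names=tuple(f"x{j + 1}" for j in range(p)))
    return SimulatedDataset(dataset, nulls, beta, sigma2)


@dataclass(frozen=True)
class SimResult:
    """Collected null statistics and rejection rates from one experiment."""

    design: SimDesign
    method: str
    criteria: tuple[str, ...]
    levels: tuple[float, ...]
    n_models: int
    n_null_tests: int
    rates: pd.DataFrame  # index: criterion, columns: levels
    mc_se: pd.DataFrame  # binomial SE of the nominal level at this size
    pvalues: Mapping[str, np.ndarray]
    seed: int
    nboot: int | None = None


def _criterion_lambdas(criteria: Sequence[str], n: int) -> list[float]:
    return [penalty_value(c, n).lam for c in criteria]


def null_mvi_distribution(
    design: SimDesign,
    n_models: int = 1000,
    seed: int = 0,
    criteria: Sequence[str] = ("AIC", "BIC", "HQIC"),
) -> dict[str, np.ndarray]:
    """Pooled null mVI draws: ``n_null`` per simulated model, per criterion.

    Under independence (rho = 0) the pooled draws are roughly chi-square(1)
    distributed for each criterion; correlation pushes mass into the upper
    tail, increasingly so for penalties that grow with n.
    """
    if n_models < 1:
        raise ValueError("n_models must be at least 1")
    lams = _criterion_lambdas(criteria, design.n)
    out = {c: np.empty(design.n_null * n_models) for c in criteria}
    children = np.random.SeedSequence(seed).spawn(n_models)
    for m, child in enumerate(children):
        sim = simulate_dataset(design, np.random.default_rng(child))
        scanner = SubsetScanner(sim.dataset.X)
        for k, v in enumerate(sim.null_indices):
            mvi = scanner.mvi_batch(sim.dataset.y, (v,), lams)[:, 0]
            for c, val in zip(criteria, mvi):
                out[c][m * design.n_null + k] = val
    for c in criteria:
        out[c] = np.maximum(out[c], 0.0)
    return out


def type1_error_rates(
    design: SimDesign,
    method: str = "naive",
    levels: Sequence[float] = (0.01, 0.05, 0.10),
    n_models: int = 1000,
    nboot: int = 100,
    seed: int = 0,
    criteria: Sequence[str] = ("AIC", "BIC", "HQIC"),
) -> SimResult:
    """Empirical type-1 error of null-variable p-values at nominal levels.

    ``naive`` refers each observed mVI to chi-square(1); ``bootstrap`` draws
    ``nboot`` parametric-bootstrap replicates per null variable per model
    (the replicate responses are shared across criteria, as only the penalty
    changes).  Rates are fractions of the pooled null p-values at or below
    each level, with the binomial standard error of the nominal level at the
    realized number of tests.
    """
    if method not in ("naive", "bootstrap"):
        raise ValueError("method must be 'naive' or 'bootstrap'")
    lams = _criterion_lambdas(criteria, design.n)
    n_tests = design.n_null * n_models
    pvals = {c: np.empty(n_tests) for c in criteria}
    children = np.random.SeedSequence(seed).spawn(n_models)
    for m, child in enumerate(children):
        rng = np.random.default_rng(child)
        sim = simulate_dataset(design, rng)
        X, y, n = sim.dataset.X, sim.dataset.y, design.n
        scanner = SubsetScanner(X)
        gram = GramCache.from_dataset(sim.dataset) if method == "bootstrap" else None
        for k, v in enumerate(sim.null_indices):
            obs = np.maximum(scanner.mvi_batch(y, (v,), lams)[:, 0], 0.0)
            if method == "naive":
                pv = stats.chi2.sf(obs, 1)
            else:
                reduced = tuple(j for j in range(design.p) if j != v)
                fit = fit_subset(gram, reduced, 0.0)
                Z = np.column_stack([np.ones(n), X[:, reduced]])
                mu = Z @ fit.coefficients
                sd = math.sqrt(fit.rss / n)
                Y = mu[:, None] + sd * rng.standard_normal((n, nboot))
                draws = np.maximum(scanner.mvi_batch(Y, (v,), lams), 0.0)
                pv = (1 + (draws >= obs[:, None]).sum(axis=1)) / (nboot + 1)
            for c, val in zip(criteria, pv):
                pvals[c][m * design.n_null + k] = val
    levels = tuple(float(a) for a in levels)
    rates = pd.DataFrame(
        {a: {c: float(np.mean(pvals[c] <= a)) for c in criteria} for a in levels}
    )
    mc_se = pd.DataFrame(
        {a: {c: math.sqrt(a * (1 - a) / n_tests) if 0 < a < 1 else 0.0 for c in criteria} for a in levels}
    )
    return SimResult(
        design=design,
        method=method,
        criteria=tuple(criteria),
        levels=levels,
        n_models=n_models,
        n_null_tests=n_tests,
        rates=rates,
        mc_se=mc_se,
        pvalues=pvals,
        seed=seed,
        nboot=nboot if method == "bootstrap" else None,
    )
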