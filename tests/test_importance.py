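import itertools
import math

import numpy as np
import pytest

from subsetvi import (
    ConsistencyError,
    GramCache,
    Penalty,
    SearchProblem,
    SubsetScanner,
    VariableGroup,
    best_subset,
    importance_table,
    modified_importance,
    penalty_value,
    singleton_groups,
    standardize_predictors,
    variable_importance,
)
from conftest import random_instance


def _problem(ds, lam, engine="branch_and_bound"):
    return SearchProblem(GramCache.from_dataset(ds), Penalty("custom", lam), engine=engine)


def _brute_vi(X, y, lam, members):
    """Oracle: enumerate all subsets, split by full-membership/no-membership."""
    n, p = X.shape
    members = set(members)
    q_inc, q_exc = np.inf, np.inf
    for k in range(p + 1):
        for comb in itertools.combinations(range(p), k):
            Z = np.column_stack([np.ones(n)] + [X[:, j] for j in comb])
            coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
            rss = float(((y - Z @ coef) ** 2).sum())
            q = n * (math.log(2 * math.pi * rss / n) + 1) + lam * k
            if members <= set(comb):
                q_inc = min(q_inc, q)
            elif not (members & set(comb)):
                q_exc = min(q_exc, q)
    return q_exc - q_inc


class TestVariableImportance:
    def test_matches_enumeration_oracle_singletons(self, rng):
        for _ in range(10):
            ds = random_instance(rng, n=100, p=6)
            lam = float(rng.choice([0.0, 2.0, math.log(ds.n)]))
            j = int(rng.integers(ds.p))
            rec = variable_importance(_problem(ds, lam), VariableGroup("g", (j,)))
            assert rec.vi == pytest.approx(_brute_vi(ds.X, ds.y, lam, (j,)), abs=1e-7)
            assert rec.mvi == pytest.approx(rec.vi + lam)

    def test_matches_enumeration_oracle_sets(self, rng):
        # "included" means every member of the set is active
        for _ in range(5):
            ds = random_instance(rng, n=80, p=6)
            members = tuple(sorted(rng.choice(6, size=2, replace=False)))
            rec = variable_importance(_problem(ds, 2.0), VariableGroup("pair", members))
            assert rec.vi == pytest.approx(_brute_vi(ds.X, ds.y, 2.0, members), abs=1e-7)
            assert rec.mvi == pytest.approx(rec.vi + 2.0 * 2)

    def test_zero_penalty_gives_likelihood_ratio_statistic(self, rng):
        # with lambda = 0 the two constrained optima are the full model and
        # the full model minus the variable, so VI is the classical LR stat
        ds = random_instance(rng, n=100, p=5)
        full = np.column_stack([np.ones(ds.n), ds.X])
        coef, *_ = np.linalg.lstsq(full, ds.y, rcond=None)
        rss_full = float(((ds.y - full @ coef) ** 2).sum())
        for j in range(ds.p):
            red = np.delete(full, j + 1, axis=1)
            coef_r, *_ = np.linalg.lstsq(red, ds.y, rcond=None)
            rss_red = float(((ds.y - red @ coef_r) ** 2).sum())
            lr = ds.n * math.log(rss_red / rss_full)
            rec = variable_importance(_problem(ds, 0.0), VariableGroup("g", (j,)))
            assert rec.vi == pytest.approx(lr, abs=1e-7)

    def test_nonnegativity_and_lower_bound(self, rng):
        # mVI >= 0 and VI >= -lambda|S| for exact engines
        for _ in range(60):
            ds = random_instance(rng)
            lam = float(rng.choice([0.0, 2.0, math.log(ds.n), 10.0]))
            size = int(rng.integers(1, min(ds.p, 3) + 1))
            members = tuple(sorted(rng.choice(ds.p, size=size, replace=False)))
            rec = variable_importance(_problem(ds, lam), VariableGroup("g", members))
            assert rec.mvi >= -1e-8
            assert rec.vi >= -lam * size - 1e-8

    def test_selection_coupling_singletons(self, rng):
        # vi > 0 exactly when the variable sits in the unconstrained optimum
        for _ in range(20):
            ds = random_instance(rng, p=6)
            lam = float(rng.choice([2.0, math.log(ds.n)]))
            problem = _problem(ds, lam)
            opt = set(best_subset(problem).active)
            for j in range(ds.p):
                rec = variable_importance(problem, VariableGroup("g", (j,)))
                assert rec.selected == (j in opt)
                assert (rec.vi > 0) == (j in opt)

    def test_invariant_to_standardization(self, rng):
        ds = random_instance(rng, n=90, p=5)
        std = standardize_predictors(ds)
        for j in range(ds.p):
            r1 = variable_importance(_problem(ds, 2.0), VariableGroup("g", (j,)))
            r2 = variable_importance(_problem(std, 2.0), VariableGroup("g", (j,)))
            assert r1.vi == pytest.approx(r2.vi, abs=1e-6)

    def test_heuristic_engine_flagged_inexact(self, rng):
        ds = random_instance(rng, p=5)
        rec = variable_importance(_problem(ds, 2.0, engine="forward"), VariableGroup("g", (0,)))
        assert not rec.exact

    def test_group_overlapping_constraints_rejected(self, rng):
        ds = random_instance(rng, p=4)
        problem = SearchProblem(
            GramCache.from_dataset(ds), Penalty("custom", 2.0), forced_in=frozenset({1})
        )
        with pytest.raises(ValueError, match="overlap"):
            variable_importance(problem, VariableGroup("g", (1,)))


class TestModifiedImportance:
    def test_value_and_lambda_guard(self, rng):
        ds = random_instance(rng, p=4)
        rec = variable_importance(_problem(ds, 2.0), VariableGroup("g", (0, 1)))
        assert modified_importance(rec, Penalty("AIC", 2.0)) == pytest.approx(rec.vi + 4.0)
        with pytest.raises(ConsistencyError):
            modified_importance(rec, Penalty("custom", 3.0))


class TestImportanceTable:
    def test_reproduces_per_group_calls(self, rng):
        ds = random_instance(rng, n=120, p=5)
        table = importance_table(ds, criteria=("AIC", "BIC"))
        for j, name in enumerate(ds.names):
            for crit in ("AIC", "BIC"):
                pen = penalty_value(crit, ds.n)
                rec = variable_importance(
                    SearchProblem(GramCache.from_dataset(ds), pen), VariableGroup(name, (j,))
                )
                assert table.loc[name, crit] == pytest.approx(rec.mvi)

    def test_long_format_carries_both_statistics(self, rng):
        ds = random_instance(rng, n=100, p=4)
        long = importance_table(ds, criteria=("AIC",), statistic="both")
        assert set(long.columns) >= {"group", "criterion", "vi", "mvi", "selected"}
        assert np.allclose(long["mvi"], long["vi"] + 2.0)

    def test_pure_noise_with_heavy_penalty_selects_nothing(self, rng):
        X = rng.standard_normal((200, 5))
        y = rng.standard_normal(200)
        from subsetvi import Dataset

        ds = Dataset(y=y, X=X, names=tuple(f"n{j}" for j in range(5)))
        long = importance_table(ds, criteria=("BIC",), statistic="both")
        assert not long["selected"].any()

    def test_scanner_agrees_with_search_engine(self, rng):
        ds = random_instance(rng, n=100, p=6)
        scanner = SubsetScanner(ds.X)
        for lam in (2.0, math.log(ds.n)):
            for j in range(ds.p):
                rec = variable_importance(_problem(ds, lam), VariableGroup("g", (j,)))
                mvi = scanner.mvi_batch(ds.y, (j,), [lam])[0, 0]
                assert mvi == pytest.approx(rec.mvi, abs=1e-8)
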