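import math

import numpy as np
import pytest
import statsmodels.api as sm

from subsetvi import (
    Dataset,
    DegenerateFitError,
    GramCache,
    InvalidPenaltyError,
    RankDeficiencyError,
    ZeroVarianceError,
    fit_subset,
    penalty_value,
    raw_coefficients,
    standardize_predictors,
    wald_squared,
)
from conftest import random_instance


class TestPenaltyValue:
    @pytest.mark.parametrize(
        "criterion, n, expected",
        [
            ("AIC", 1000, 2.0),
            ("aic", 5, 2.0),
            ("BIC", 1, 0.0),  # log 1 = 0
            ("BIC", 1000, math.log(1000)),
            ("HQIC", 1000, 2.0 * math.log(math.log(1000.0))),
        ],
    )
    def test_criterion_lambdas(self, criterion, n, expected):
        pen = penalty_value(criterion, n)
        assert pen.lam == pytest.approx(expected, abs=1e-12)

    def test_custom_passes_through(self):
        assert penalty_value("custom", lam=3.7).lam == 3.7

    @pytest.mark.parametrize(
        "criterion, n, lam",
        [("HQIC", 2, None), ("custom", None, -1.0), ("nope", 10, None)],
    )
    def test_invalid_specifications(self, criterion, n, lam):
        with pytest.raises(InvalidPenaltyError):
            penalty_value(criterion, n=n, lam=lam)


class TestFitSubset:
    def test_intercept_only_closed_form(self, rng):
        ds = random_instance(rng, n=60, p=3)
        fit = fit_subset(GramCache.from_dataset(ds), (), lam=2.0)
        assert fit.coefficients[0] == pytest.approx(ds.y.mean())
        assert fit.rss == pytest.approx(((ds.y - ds.y.mean()) ** 2).sum())
        assert fit.q == fit.neg2ll  # empty active set pays no penalty

    def test_two_point_profile_likelihood(self):
        ds = Dataset(y=np.array([-1.0, 1.0]), X=np.array([[0.3], [0.4]]), names=("a",))
        fit = fit_subset(GramCache.from_dataset(ds), (), 0.0)
        assert fit.rss == pytest.approx(2.0)
        # sigma2_hat = 1, so -2loglik = n*(log(2*pi) + 1)
        assert fit.neg2ll == pytest.approx(2 * (math.log(2 * math.pi) + 1))

    def test_matches_dense_least_squares_oracle(self, rng):
        for _ in range(100):
            ds = random_instance(rng, p=int(rng.integers(1, 11)))
            gram = GramCache.from_dataset(ds)
            k = int(rng.integers(0, ds.p + 1))
            active = tuple(sorted(rng.choice(ds.p, size=k, replace=False)))
            fit = fit_subset(gram, active, 2.0)
            Z = np.column_stack([np.ones(ds.n), ds.X[:, list(active)]])
            coef, *_ = np.linalg.lstsq(Z, ds.y, rcond=None)
            rss = float(((ds.y - Z @ coef) ** 2).sum())
            assert fit.coefficients == pytest.approx(coef, rel=1e-8, abs=1e-8)
            assert fit.rss == pytest.approx(rss, rel=1e-8)

    def test_nesting_never_increases_rss(self, rng):
        for _ in range(25):
            ds = random_instance(rng)
            gram = GramCache.from_dataset(ds)
            k = int(rng.integers(0, ds.p))
            active = tuple(sorted(rng.choice(ds.p, size=k, replace=False)))
            extra = int(rng.choice([j for j in range(ds.p) if j not in active]))
            small = fit_subset(gram, active, 0.0)
            big = fit_subset(gram, active + (extra,), 0.0)
            assert big.rss <= small.rss + 1e-9 * small.rss
            assert big.neg2ll <= small.neg2ll + 1e-8

    def test_q_differences_invariant_to_affine_predictor_maps(self, rng):
        ds = random_instance(rng, n=80, p=4)
        shifted = Dataset(
            y=ds.y, X=ds.X * np.array([2.0, 0.5, 3.0, 1.0]) + 7.0, names=ds.names
        )
        g1, g2 = GramCache.from_dataset(ds), GramCache.from_dataset(shifted)
        a, b = (0, 2), (1, 2, 3)
        lam = math.log(ds.n)
        d1 = fit_subset(g1, a, lam).q - fit_subset(g1, b, lam).q
        d2 = fit_subset(g2, a, lam).q - fit_subset(g2, b, lam).q
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_duplicate_column_raises_rank_deficiency(self, rng):
        X = rng.standard_normal((50, 2))
        X = np.column_stack([X, X[:, 0]])
        ds = Dataset(y=rng.standard_normal(50), X=X, names=("a", "b", "c"))
        with pytest.raises(RankDeficiencyError):
            fit_subset(GramCache.from_dataset(ds), (0, 1, 2), 2.0)

    def test_perfect_fit_is_degenerate(self, rng):
        X = rng.standard_normal((20, 2))
        ds = Dataset(y=X @ np.array([1.0, -2.0]) + 3.0, X=X, names=("a", "b"))
        with pytest.raises(DegenerateFitError):
            fit_subset(GramCache.from_dataset(ds), (0, 1), 2.0)

    def test_refresh_y_reproduces_fresh_cache(self, rng):
        ds = random_instance(rng, n=70, p=5)
        gram = GramCache.from_dataset(ds)
        y2 = rng.standard_normal(ds.n)
        gram.refresh_y(ds.X, y2)
        fresh = GramCache.from_arrays(ds.X, y2)
        assert gram.G == pytest.approx(fresh.G, rel=1e-10)


class TestWaldSquared:
    def test_equals_squared_t_from_statsmodels(self, rng):
        ds = random_instance(rng, n=40, p=4)
        res = sm.OLS(ds.y, sm.add_constant(ds.X)).fit()
        for j in range(ds.p):
            assert wald_squared(ds, (j,)) == pytest.approx(res.tvalues[j + 1] ** 2)

    def test_group_statistic_matches_f_test(self, rng):
        ds = random_instance(rng, n=60, p=5)
        res = sm.OLS(ds.y, sm.add_constant(ds.X)).fit()
        R = np.zeros((2, ds.p + 1))
        R[0, 2] = R[1, 4] = 1.0
        f = float(np.squeeze(res.f_test(R).fvalue))
        assert wald_squared(ds, (1, 3)) == pytest.approx(2 * f)

    def test_invariant_to_positive_column_rescaling(self, rng):
        ds = random_instance(rng, n=50, p=3)
        scaled = Dataset(y=ds.y, X=ds.X * np.array([10.0, 0.01, 1.0]), names=ds.names)
        for j in range(3):
            assert wald_squared(ds, (j,)) == pytest.approx(wald_squared(scaled, (j,)))


class TestStandardize:
    def test_unit_variance_and_idempotence(self, rng):
        ds = standardize_predictors(random_instance(rng, n=90, p=4))
        assert ds.X.mean(axis=0) == pytest.approx(np.zeros(4), abs=1e-12)
        assert ds.X.std(axis=0, ddof=1) == pytest.approx(np.ones(4))
        again = standardize_predictors(ds)
        assert again.X == pytest.approx(ds.X, abs=1e-12)

    def test_slope_scales_by_column_sd(self, rng):
        ds = random_instance(rng, n=120, p=3)
        std = standardize_predictors(ds)
        raw_fit = fit_subset(GramCache.from_dataset(ds), (0, 2), 0.0)
        std_fit = fit_subset(GramCache.from_dataset(std), (0, 2), 0.0)
        sds = ds.X.std(axis=0, ddof=1)
        assert std_fit.coefficients[1:] == pytest.approx(
            raw_fit.coefficients[1:] * sds[[0, 2]]
        )

    def test_raw_coefficients_recoverable(self, rng):
        ds = random_instance(rng, n=100, p=5)
        std = standardize_predictors(ds)
        active = (1, 3, 4)
        back = raw_coefficients(std, fit_subset(GramCache.from_dataset(std), active, 0.0))
        direct = fit_subset(GramCache.from_dataset(ds), active, 0.0).coefficients
        assert back == pytest.approx(direct, rel=1e-8, abs=1e-10)

    def test_constant_column_rejected(self, rng):
        X = np.column_stack([rng.standard_normal(30), np.full(30, 2.0)])
        ds = Dataset(y=rng.standard_normal(30), X=X, names=("a", "b"))
        with pytest.raises(ZeroVarianceError):
            standardize_predictors(ds)


class TestDatasetValidation:
    def test_rejects_missing_values(self):
        with pytest.raises(ValueError, match="missing"):
            Dataset(y=np.array([1.0, np.nan]), X=np.ones((2, 1)), names=("a",))

    def test_rejects_duplicate_labels(self):
        with pytest.raises(ValueError, match="unique"):
            Dataset(y=np.ones(3), X=np.ones((3, 2)), names=("a", "a"))
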