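"""Multivariate-normal imputation: EM fixed points, closed-form oracles,
data-augmentation contracts, and Mardia's kurtosis test."""

import numpy as np
import pytest
from scipy import stats

from morphodelim import (da_impute, em_mvn, kurtosis_normality_test,
                         missing_fraction, prune_missing)
from conftest import make_measurements


class TestMissingFraction:
    def test_fully_observed_is_zero(self, rng):
        m = make_measurements(rng.uniform(1, 10, (4, 5)))
        assert missing_fraction(m) == 0.0

    def test_exact_rational(self, rng):
        vals = rng.uniform(1, 10, (4, 5))
        vals[0, 0] = np.nan
        vals[2, 3] = np.nan
        assert missing_fraction(make_measurements(vals)) == 0.10

    def test_empty_matrix_is_error(self):
        import pandas as pd

        from morphodelim import MeasurementMatrix
        with pytest.raises(ValueError):
            MeasurementMatrix(pd.DataFrame())


class TestPruning:
    def test_drops_sparse_variable_then_specimen(self, rng):
        vals = rng.uniform(1, 10, (6, 3))
        vals[:4, 2] = np.nan          # variable observed in 2/6 < 50%
        vals[5, 0] = vals[5, 1] = np.nan  # specimen then observed in 0/2
        m = make_measurements(vals)
        pruned, log = prune_missing(m)
        assert pruned.n_variables == 2
        assert "s5" not in pruned.specimen_ids
        assert {e[0] for e in log} == {"variable", "specimen"}


class TestEM:
    def test_complete_data_fixed_point(self, rng):
        X = rng.uniform(5, 50, (20, 3))
        params = em_mvn(make_measurements(X))
        assert np.allclose(params.mean, X.mean(axis=0))
        assert np.allclose(params.covariance,
                           np.cov(X, rowvar=False, bias=True), atol=1e-6)

    def test_single_missing_cell_matches_conditional_normal(self, rng):
        # monotone pattern with one missing cell: the ML solution factors
        # into N(v1) times the complete-case regression of v2 on v1
        n = 40
        x1 = rng.normal(100, 10, n)
        x2 = 0.8 * x1 + rng.normal(0, 3, n) + 20
        X = np.column_stack([x1, x2])
        X[-1, 1] = np.nan
        params = em_mvn(make_measurements(X), tol=1e-12, max_iter=2000)

        # oracle: factored-regression ML estimates
        mu1 = x1.mean()
        s11 = x1.var()
        cc = X[:-1]  # complete cases
        beta = np.polyfit(cc[:, 0], cc[:, 1], 1)
        resid = cc[:, 1] - np.polyval(beta, cc[:, 0])
        mu2 = np.polyval(beta, mu1)
        s12 = beta[0] * s11
        s22 = resid.var() + beta[0] ** 2 * s11
        assert np.allclose(params.mean, [mu1, mu2], rtol=1e-6)
        assert np.allclose(params.covariance,
                           [[s11, s12], [s12, s22]], rtol=1e-4)
        # the conditional expectation of the missing cell is the
        # regression prediction
        pred = params.mean[1] + params.covariance[0, 1] / params.covariance[0, 0] \
            * (X[-1, 0] - params.mean[0])
        assert np.isclose(pred, np.polyval(beta, X[-1, 0]), rtol=1e-6)

    def test_monotone_missingness_matches_factored_ml(self, rng):
        n = 60
        X = rng.multivariate_normal([50, 60, 70],
                                    [[25, 10, 5], [10, 25, 8], [5, 8, 25]], n)
        X[40:, 2] = np.nan  # monotone: v3 missing in the last third
        params = em_mvn(make_measurements(X), tol=1e-12, max_iter=5000)
        mu12 = X[:, :2].mean(axis=0)
        S12 = np.cov(X[:, :2], rowvar=False, bias=True)
        cc = X[:40]
        A = np.column_stack([np.ones(40), cc[:, :2]])
        coef, *_ = np.linalg.lstsq(A, cc[:, 2], rcond=None)
        resid = cc[:, 2] - A @ coef
        b = coef[1:]
        mu3 = coef[0] + b @ mu12
        S13 = S12 @ b
        S33 = resid.var() + b @ S12 @ b
        assert np.allclose(params.mean, [*mu12, mu3], rtol=1e-6)
        assert np.allclose(params.covariance[:2, :2], S12, rtol=1e-6)
        assert np.allclose(params.covariance[2, :2], S13, rtol=1e-4)
        assert np.isclose(params.covariance[2, 2], S33, rtol=1e-4)

    def test_underobserved_variable_is_error(self, rng):
        vals = rng.uniform(1, 10, (5, 2))
        vals[1:, 1] = np.nan
        with pytest.raises(ValueError, match="fewer than 2"):
            em_mvn(make_measurements(vals))


class TestDataAugmentation:
    def test_no_missing_is_identity(self, rng):
        m = make_measurements(rng.uniform(5, 50, (15, 3)))
        res = da_impute(m, steps=100, seed=1)
        assert res.completed == m
        assert res.chain_length == 0

    def test_observed_cells_never_altered_and_deterministic(self, rng):
        vals = rng.uniform(5, 50, (25, 4))
        holes = rng.random(vals.shape) < 0.25
        vals[holes] = np.nan
        m = make_measurements(vals)
        r1 = da_impute(m, steps=30, seed=7)
        r2 = da_impute(m, steps=30, seed=7)
        assert r1.completed == r2.completed          # bit-identical per seed
        obs = ~m.mask
        assert np.array_equal(r1.completed.values[obs], m.values[obs])
        r3 = da_impute(m, steps=30, seed=8)
        assert r3.completed != r1.completed          # seed matters

    def test_mcar_mean_bias_small(self, rng):
        truth_mean = np.array([50.0, 80.0, 40.0, 60.0, 30.0])
        cov = 25 * (0.5 * np.ones((5, 5)) + 0.5 * np.eye(5))
        X = rng.multivariate_normal(truth_mean, cov, size=200)
        holes = rng.random(X.shape) < 0.20
        X = X.copy()
        X[holes] = np.nan
        m = make_measurements(X)
        res = da_impute(m, steps=100, seed=11)
        sd = np.sqrt(np.diag(cov))
        bias = np.abs(res.completed.values.mean(axis=0) - truth_mean)
        assert np.all(bias < 0.1 * sd)

    def test_parameter_recovery_improves_with_n(self, rng):
        # study-level missingness (25-41%): completed-data moments approach
        # the generating parameters as the sample grows
        truth_mean = np.array([100.0, 60.0, 30.0])
        cov = np.array([[100, 40, 20], [40, 64, 16], [20, 16, 36.0]])
        errs = {}
        for n in (100, 400):
            X = rng.multivariate_normal(truth_mean, cov, size=n)
            holes = rng.random(X.shape) < 0.33
            X[holes] = np.nan
            res = da_impute(make_measurements(X), steps=100, seed=5)
            C = res.completed.values
            errs[n] = (np.abs(C.mean(axis=0) - truth_mean).max(),
                       np.abs(np.cov(C, rowvar=False) - cov).max())
        assert errs[400][0] < errs[100][0] * 1.5     # no blow-up
        assert errs[400][0] < 2.0                    # close in absolute terms


class TestMardia:
    def test_statistic_matches_brute_force(self):
        X = np.array([[2.0, 5.0], [3.0, 7.0], [4.0, 6.0],
                      [5.0, 9.0], [6.0, 8.0]])
        m = make_measurements(X)
        b2p, z, p = kurtosis_normality_test(m)
        # independent evaluation of the formula
        n, d = X.shape
        mu = X.mean(axis=0)
        S = sum(np.outer(x - mu, x - mu) for x in X) / n
        Sinv = np.linalg.inv(S)
        md = [float((x - mu) @ Sinv @ (x - mu)) for x in X]
        b_expected = np.mean([v ** 2 for v in md])
        z_expected = (b_expected - d * (d + 2)) / np.sqrt(8 * d * (d + 2) / n)
        assert np.isclose(b2p, b_expected)
        assert np.isclose(z, z_expected)
        assert np.isclose(p, 2 * stats.norm.sf(abs(z_expected)))

    def test_large_mvn_sample_near_expectation(self, rng):
        X = rng.multivariate_normal(np.full(3, 50.0), np.eye(3) * 4, 5000)
        b2p, _, _ = kurtosis_normality_test(make_measurements(X))
        assert abs(b2p - 15.0) / 15.0 < 0.02

    def test_heavy_tails_detected(self, rng):
        X = 100 + stats.t(df=3).rvs(size=(500, 2),
                                    random_state=np.random.RandomState(4))
        _, _, p = kurtosis_normality_test(make_measurements(np.abs(X)))
        assert p < 0.01

    def test_incomplete_matrix_is_error(self, rng):
        vals = rng.uniform(1, 10, (6, 2))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            kurtosis_normality_test(make_measurements(vals))
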