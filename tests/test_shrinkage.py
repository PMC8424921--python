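"""Sample correlation, shrinkage map, and shrunk partial correlations."""

import numpy as np
import pytest

from unshrunk import (
    DataMatrix,
    condition_number,
    estimate_optimal_lambda,
    partial_correlation_from_precision,
    sample_correlation,
    shrink_correlation,
    shrunk_partial_correlation,
)
from unshrunk.toys import PITFALL_COVARIANCE, pitfall_precision_fractions

from conftest import model_from_matrix


class TestSampleCorrelation:
    def test_matches_pairwise_pearson_oracle(self, gaussian_data):
        data = gaussian_data(200, 4, correlated=True)
        R = sample_correlation(data).R_sample
        X = data.values
        n = data.n
        for i in range(4):
            for j in range(4):
                xi, xj = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                si = np.sqrt((xi**2).sum() / (n - 1))
                sj = np.sqrt((xj**2).sum() / (n - 1))
                r = (xi * xj).sum() / ((n - 1) * si * sj)
                assert R[i, j] == pytest.approx(r, abs=1e-12)

    def test_duplicated_and_negated_columns(self, rng):
        x = rng.standard_normal(50)
        data = DataMatrix(np.column_stack([x, x, -x, rng.standard_normal(50)]))
        R = sample_correlation(data).R_sample
        assert R[0, 1] == pytest.approx(1.0)
        assert R[0, 2] == pytest.approx(-1.0)

    def test_singular_input_accepted(self, singular_model):
        model = singular_model(4, 7, seed=0)
        assert model.is_singular()
        assert model.eigenvalues.min() >= 0.0

    def test_zero_variance_column_named_in_error(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 2.5
        data = DataMatrix(X, ["a", "flat", "c"])
        with pytest.raises(ValueError, match="flat"):
            sample_correlation(data)

    def test_missing_values_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        X[3, 1] = np.nan
        with pytest.raises(ValueError, match="missing|non-finite"):
            DataMatrix(X)


class TestOptimalLambda:
    @staticmethod
    def _oracle(X):
        """Loop-based Schaefer-Strimmer evaluation, independent route."""
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        n, p = X.shape
        num = den = 0.0
        for i in range(p):
            for j in range(i + 1, p):
                w = X[:, i] * X[:, j]
                wbar = w.mean()
                r = n / (n - 1) * wbar
                var = n / (n - 1) ** 3 * ((w - wbar) ** 2).sum()
                num += var
                den += r**2
        return min(1.0, max(0.0, num / den))

    def test_matches_direct_formula(self, gaussian_data):
        data = gaussian_data(40, 6, correlated=True)
        assert estimate_optimal_lambda(data) == pytest.approx(
            self._oracle(data.values), abs=1e-12
        )

    def test_vanishes_for_large_samples_with_real_structure(self):
        rng = np.random.default_rng(7)
        C = np.eye(5)
        C[0, 1] = C[1, 0] = 0.6
        C[2, 3] = C[3, 2] = -0.5
        X = rng.multivariate_normal(np.zeros(5), C, size=10_000)
        assert estimate_optimal_lambda(DataMatrix(X)) < 0.05

    def test_near_one_for_independent_small_sample(self, gaussian_data):
        lam = estimate_optimal_lambda(gaussian_data(8, 30, seed=3))
        assert lam > 0.8

    def test_requires_three_samples(self, gaussian_data):
        with pytest.raises(ValueError):
            estimate_optimal_lambda(gaussian_data(2, 4))


class TestShrinkCorrelation:
    def test_endpoints(self, singular_model):
        model = singular_model(10, 4, seed=1)
        assert np.allclose(shrink_correlation(model, 0.0).R_shrunk, model.R_sample)
        assert np.allclose(shrink_correlation(model, 1.0).R_shrunk, np.eye(4))

    def test_all_ones_off_diagonal_pattern(self):
        model = model_from_matrix(np.ones((3, 3)))
        for lam in (0.2, 1 / 3, 0.8):
            shrunk = shrink_correlation(model, lam).R_shrunk
            off = shrunk[~np.eye(3, dtype=bool)]
            assert np.allclose(off, 1 - lam)

    def test_eigenvalue_map_and_eigenvector_invariance(self, singular_model):
        model = singular_model(6, 9, seed=2)
        for lam in (0.1, 0.5, 0.9):
            shrunk = shrink_correlation(model, lam)
            expected = (1 - lam) * model.eigenvalues + lam
            got = np.linalg.eigvalsh(shrunk.R_shrunk)[::-1]
            assert np.allclose(got, expected, atol=1e-10)
            assert got.min() > 0
            # eigenvectors unchanged: subspace angle of leading vector
            v = model.eigenvectors[:, 0]
            w = np.linalg.eigh(shrunk.R_shrunk)[1][:, -1]
            assert abs(abs(v @ w) - 1.0) < 1e-8

    def test_lambda_out_of_range(self, singular_model):
        model = singular_model(10, 4, seed=1)
        for lam in (-0.1, 1.2):
            with pytest.raises(ValueError):
                shrink_correlation(model, lam)


class TestPartialCorrelation:
    def test_printed_matrix_via_rational_oracle(self):
        # exact fraction arithmetic gives the expected standardized entries
        from fractions import Fraction
        from math import sqrt

        O = pitfall_precision_fractions()
        p12 = float(-O[0][1]) / sqrt(float(O[0][0]) * float(O[1][1]))
        p34 = float(-O[2][3]) / sqrt(float(O[2][2]) * float(O[3][3]))
        P = partial_correlation_from_precision(np.linalg.inv(PITFALL_COVARIANCE))
        assert P.values[0, 1] == pytest.approx(p12, abs=1e-12)
        assert P.values[2, 3] == pytest.approx(p34, abs=1e-12)
        # and the standardized ratios evaluate to 0.59 / 0.38 at two decimals
        assert round(p12, 2) == 0.59
        assert round(p34, 2) == 0.38

    def test_diagonal_precision_gives_zero_pcors(self):
        P = partial_correlation_from_precision(np.diag([2.0, 3.0, 4.0]))
        assert np.allclose(P.values, np.eye(3))

    def test_nonpositive_diagonal_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation_from_precision(np.diag([1.0, -1.0]))

    def test_eigen_route_equals_dense_inverse(self, gaussian_data):
        model = sample_correlation(gaussian_data(80, 6, correlated=True))
        for lam in (0.0, 0.05, 0.3, 0.9):
            via_eigen = shrunk_partial_correlation(model, lam).values
            R = (1 - lam) * model.R_sample + lam * np.eye(6)
            via_inverse = partial_correlation_from_precision(np.linalg.inv(R)).values
            assert np.abs(via_eigen - via_inverse).max() < 1e-10

    def test_two_variables_reduce_to_pearson(self, gaussian_data):
        data = gaussian_data(60, 2, correlated=True)
        model = sample_correlation(data)
        P = shrunk_partial_correlation(model, 0.0)
        assert P.values[0, 1] == pytest.approx(model.R_sample[0, 1], abs=1e-12)

    def test_zero_lambda_on_singular_input_redirects(self, singular_model):
        model = singular_model(4, 8, seed=5)
        with pytest.raises(np.linalg.LinAlgError, match="unshrink"):
            shrunk_partial_correlation(model, 0.0)


class TestConditionNumber:
    def test_identity_and_singular(self):
        assert condition_number(model_from_matrix(np.eye(4))) == 1.0
        assert condition_number(model_from_matrix(np.ones((3, 3)))) == np.inf

    def test_ratio_of_extreme_eigenvalues(self, gaussian_data):
        model = sample_correlation(gaussian_data(100, 5, correlated=True))
        ev = np.linalg.eigvalsh(model.R_sample)
        assert condition_number(model) == pytest.approx(ev.max() / ev.min(), rel=1e-10)


class TestPitfallMatrix:
    """Printed 4x4 worked example: spectrum and derived scalars."""

    def test_spectrum_and_determinant(self):
        ev = np.sort(np.linalg.eigvalsh(PITFALL_COVARIANCE))[::-1]
        assert np.round(ev, 2).tolist() == [2.66, 0.94, 0.25, 0.15]
        assert round(float(np.linalg.det(PITFALL_COVARIANCE)), 2) == 0.09

    def test_condition_number_matches_eigenvalue_ratio(self):
        model = model_from_matrix(PITFALL_COVARIANCE)
        ev = np.linalg.eigvalsh(PITFALL_COVARIANCE)
        assert condition_number(model) == pytest.approx(ev.max() / ev.min(), rel=1e-12)
        assert condition_number(model) == pytest.approx(17.54, abs=0.005)
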