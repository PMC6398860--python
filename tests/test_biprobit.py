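"""Bivariate probit: orthant probabilities, joint likelihood, sensitivity."""
import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from schoolhiv._bvn import bvn_cdf, bvn_pdf
from schoolhiv.biprobit import (
    BiprobitParams,
    biprobit_loglik,
    cell_probabilities,
    fit_biprobit,
    fit_constrained_biprobit,
    selection_upper_bound,
    sensitivity_grid,
)
from schoolhiv.exceptions import InvalidParameterError, UndefinedBoundError
from schoolhiv.probit import discrete_change_at_means, fit_probit


def _quad_bvn(h, k, rho):
    def dens(y, x):
        return bvn_pdf(x, y, rho)

    val, _ = integrate.dblquad(dens, -8.5, h, -8.5, k, epsabs=1e-11)
    return val


class TestBvnCdf:
    def test_against_quadrature(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            h, k = rng.normal(0, 1.5, 2)
            rho = rng.uniform(-0.95, 0.95)
            assert abs(float(bvn_cdf(h, k, rho)) - _quad_bvn(h, k, rho)) < 1e-8

    def test_zero_zero_arcsine_formula(self):
        for rho in (-0.9, -0.3, 0.0, 0.5):
            expected = 0.25 + np.arcsin(rho) / (2 * np.pi)
            assert abs(float(bvn_cdf(0.0, 0.0, rho)) - expected) < 1e-14

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            bvn_cdf(0.0, 0.0, 1.0)


class TestCellProbabilities:
    def test_symmetric_independent_quarters(self):
        cells = cell_probabilities(0.0, 0.0, 0.0, 0.0)
        assert np.allclose(cells, 0.25, atol=1e-14)

    def test_conservation_over_random_draws(self):
        rng = np.random.default_rng(1)
        a, b0 = rng.normal(0, 2, (2, 1000))
        beta = rng.normal(0, 1, 1000)
        rho = rng.uniform(-0.99, 0.99, 1000)
        total = np.zeros(1000)
        for i in range(1000):
            total[i] = sum(float(c) for c in
                           cell_probabilities(a[i], b0[i], beta[i], rho[i]))
        assert np.max(np.abs(total - 1.0)) < 1e-10

    def test_against_orthant_quadrature(self):
        a, b0, beta, rho = 0.3, -0.2, 0.5, -0.4
        p11, p10, p01, p00 = (float(c) for c in
                              cell_probabilities(a, b0, beta, rho))
        b1 = b0 + beta
        q11 = _quad_bvn(a, b1, rho)
        assert abs(p11 - q11) < 1e-8
        assert abs(p10 - (norm.cdf(a) - q11)) < 1e-8
        q = _quad_bvn(a, b0, rho)
        assert abs(p01 - (norm.cdf(b0) - q)) < 1e-8
        assert abs(p00 - (1 - norm.cdf(a) - norm.cdf(b0) + q)) < 1e-8


def _sim_system(n, rho, beta, seed, gamma=(0.9, -0.3)):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    Z = np.column_stack([(rng.random(n) < 0.7).astype(float),
                         rng.exponential(1.0, n)])
    delta, pi = np.array([0.3, 0.4]), np.array([-1.2, 0.3])
    L = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
    e = rng.standard_normal((n, 2)) @ L.T
    s = (X @ delta + Z @ np.asarray(gamma) + e[:, 0] > 0).astype(float)
    y = (X @ pi + beta * s + e[:, 1] > 0).astype(float)
    return y, s, X, Z


class TestJointLoglik:
    def test_factorizes_at_rho_zero(self):
        y, s, X, Z = _sim_system(3000, -0.3, 0.4, 0)
        params = BiprobitParams(delta=np.array([0.3, 0.4]),
                                gamma=np.array([0.9, -0.3]),
                                pi=np.array([-1.2, 0.3]), beta=0.4, rho=0.0)
        joint = biprobit_loglik(params, y, s, X, Z)
        from schoolhiv.probit import probit_loglik

        sep = (probit_loglik(np.r_[params.delta, params.gamma], s, np.hstack([X, Z]))
               + probit_loglik(np.r_[params.pi, params.beta], y,
                               np.hstack([X, s[:, None]])))
        assert abs(joint - sep) < 1e-10

    def test_matches_quadrature_cells_on_small_data(self):
        y, s, X, Z = _sim_system(20, -0.4, 0.5, 1)
        params = BiprobitParams(delta=np.array([0.2, 0.3]),
                                gamma=np.array([0.5, -0.2]),
                                pi=np.array([-0.8, 0.2]), beta=0.5, rho=-0.4)
        a = X @ params.delta + Z @ params.gamma
        b0 = X @ params.pi
        total = 0.0
        for i in range(20):
            cells = cell_probabilities(a[i], b0[i], params.beta, params.rho)
            total += np.log(float(cells[int(2 * (1 - s[i]) + (1 - y[i]))]))
        assert abs(biprobit_loglik(params, y, s, X, Z) - total) < 1e-8

    def test_permutation_invariance(self):
        y, s, X, Z = _sim_system(200, -0.4, 0.5, 2)
        params = BiprobitParams(delta=np.array([0.2, 0.3]),
                                gamma=np.array([0.5, -0.2]),
                                pi=np.array([-0.8, 0.2]), beta=0.5, rho=-0.4)
        ll = biprobit_loglik(params, y, s, X, Z)
        perm = np.random.default_rng(0).permutation(200)
        ll_perm = biprobit_loglik(params, y[perm], s[perm], X[perm], Z[perm])
        # identical terms, summation order differs only at float rounding
        assert abs(ll_perm - ll) < 1e-9


class TestFitBiprobit:
    def test_truth_not_better_than_optimum(self):
        y, s, X, Z = _sim_system(4000, -0.3, 0.4, 3)
        clusters = np.arange(len(y))
        fit = fit_biprobit(y, s, X, Z, clusters)
        truth = BiprobitParams(delta=np.array([0.3, 0.4]),
                               gamma=np.array([0.9, -0.3]),
                               pi=np.array([-1.2, 0.3]), beta=0.4, rho=-0.3)
        assert biprobit_loglik(truth, y, s, X, Z) <= fit.loglik + 1e-6

    def test_recovers_parameters_single_draw(self):
        y, s, X, Z = _sim_system(20000, -0.3, 0.4, 4)
        fit = fit_biprobit(y, s, X, Z, np.arange(len(y)))
        assert fit.converged
        assert abs(fit.params.rho - (-0.3)) < 0.15
        assert abs(fit.params.beta - 0.4) < 0.3

    def test_wald_and_lr_tests_agree(self):
        y, s, X, Z = _sim_system(20000, -0.3, 0.0, 5)
        clusters = np.arange(len(y))
        fit = fit_biprobit(y, s, X, Z, clusters)
        # LR against the rho = 0 factorized model (same regressors)
        s_fit = fit_probit(s, np.hstack([X, Z]), clusters)
        y_fit = fit_probit(y, np.hstack([X, s[:, None]]), clusters)
        from scipy.stats import chi2

        lr = 2.0 * (fit.loglik - s_fit.loglik - y_fit.loglik)
        p_lr = float(chi2.sf(max(lr, 0.0), 1))
        assert abs(p_lr - fit.rho_test_p) < 0.02


class TestConstrainedAndGrid:
    def test_phi_zero_equals_univariate_probit(self):
        y, s, X, _ = _sim_system(4000, -0.3, 0.4, 6)
        clusters = np.arange(len(y))
        cfit = fit_constrained_biprobit(y, s, X, 0.0, clusters)
        ufit = fit_probit(y, np.hstack([X, s[:, None]]), clusters,
                          names=["const", "x", "attendance"])
        upe = discrete_change_at_means(ufit, "attendance")
        assert abs(cfit.params.beta - ufit.params[-1]) < 1e-6
        assert abs(cfit.partial_effect.estimate - upe.estimate) < 1e-6

    def test_phi_at_truth_unbiased(self):
        """Data from the no-instrument system itself: imposing the true
        correlation recovers beta without bias."""
        errs = []
        for r in range(20):
            y, s, X, _ = _sim_system(6000, -0.3, 0.4, 100 + r, gamma=(0.0, 0.0))
            cfit = fit_constrained_biprobit(y, s, X, -0.3, np.arange(len(y)))
            errs.append(cfit.params.beta - 0.4)
        errs = np.array(errs)
        assert abs(errs.mean()) < 2.0 * errs.std(ddof=1) / np.sqrt(len(errs))

    def test_grid_structure_and_monotonicity(self):
        y, s, X, _ = _sim_system(8000, -0.3, -0.3, 7)
        grid = sensitivity_grid(y, s, X, np.arange(len(y)),
                                grid=(0.0, -0.1, -0.2, -0.3))
        phis = [e.phi for e in grid.entries]
        assert phis[0] == 0.0
        assert len(grid.entries) == 5  # four requested + appended bound
        assert grid.entries[-1].is_bound
        effects = [e.partial_effect for e in grid.entries[:-1]]
        assert all(np.diff(effects[::-1]) <= 1e-4)  # nonincreasing in phi

    def test_invalid_phi_rejected(self):
        y, s, X, _ = _sim_system(200, 0.0, 0.0, 8)
        with pytest.raises(InvalidParameterError):
            fit_constrained_biprobit(y, s, X, 1.0, np.arange(len(y)))


class _MockSchool:
    def __init__(self, params):
        self.params = np.asarray(params, dtype=float)


class _MockOutcome:
    class _P:
        pass

    def __init__(self, pi):
        self.params = self._P()
        self.params.pi = np.asarray(pi, dtype=float)


class TestSelectionBound:
    def test_proportional_indices(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(200), rng.normal(size=200)])
        pi = np.array([0.5, 1.0])
        bound = selection_upper_bound(_MockSchool(2 * pi), _MockOutcome(pi), X)
        assert abs(bound.rho_upper - 2.0) < 1e-12

    def test_orthogonal_indices(self):
        n = 400
        x1 = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        x2 = np.tile([1.0, -1.0], n // 2)
        X = np.column_stack([x1, x2])  # exactly orthogonal, zero-mean columns
        bound = selection_upper_bound(_MockSchool([1.0, 0.0]),
                                      _MockOutcome([0.0, 1.0]), X)
        assert abs(bound.rho_upper) < 1e-12

    def test_degenerate_outcome_index(self):
        X = np.ones((50, 1))
        with pytest.raises(UndefinedBoundError):
            selection_upper_bound(_MockSchool([1.0]), _MockOutcome([1.0]), X)
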