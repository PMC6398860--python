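"""Linear suite: OLS, fixed effects, LIML, coefficient stability."""
import numpy as np
import pytest
from scipy.optimize import brentq

from schoolhiv.exceptions import InvalidParameterError
from schoolhiv.linear import delta_star, fit_fe_within, fit_liml, fit_lpm


def _panel_data(n_persons=50, t=4, seed=0, confounded=False):
    rng = np.random.default_rng(seed)
    pid = np.repeat(np.arange(n_persons), t)
    a = rng.normal(0, 1, n_persons)[pid]
    x = rng.normal(size=n_persons * t) + (a if confounded else 0.0)
    y = 0.5 * x + a + rng.normal(size=n_persons * t)
    X = np.column_stack([np.ones(len(y)), x])
    return y, X, pid


class TestLPM:
    def test_intercept_only_is_mean(self):
        rng = np.random.default_rng(0)
        y = (rng.random(500) < 0.3).astype(float)
        fit = fit_lpm(y, np.ones((500, 1)), np.arange(500))
        assert fit.params[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_normal_equations_closed_form(self):
        y, X, _ = _panel_data(seed=1)
        fit = fit_lpm(y, X, np.arange(len(y)))
        closed = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.max(np.abs(fit.params - closed)) < 1e-10

    def test_cluster_se_against_pairs_bootstrap(self):
        y, X, pid = _panel_data(n_persons=60, t=5, seed=2)
        fit = fit_lpm(y, X, pid)
        rng = np.random.default_rng(0)
        ids = np.unique(pid)
        boots = []
        for _ in range(1000):
            chosen = rng.choice(ids, size=len(ids), replace=True)
            rows = np.concatenate([np.nonzero(pid == c)[0] for c in chosen])
            b = np.linalg.lstsq(X[rows], y[rows], rcond=None)[0]
            boots.append(b[1])
        boot_se = np.std(boots, ddof=1)
        assert abs(fit.se("x1") - boot_se) / boot_se < 0.15


class TestFixedEffects:
    def test_equals_lsdv(self):
        y, X, pid = _panel_data(n_persons=50, t=4, seed=3, confounded=True)
        fe = fit_fe_within(y, X, pid, pid)
        dummies = np.equal.outer(pid, np.unique(pid)).astype(float)
        lsdv = np.linalg.lstsq(np.column_stack([X[:, 1:], dummies]), y,
                               rcond=None)[0]
        assert abs(fe.coef("x1") - lsdv[0]) < 1e-8

    def test_within_transform_invariance(self):
        y, X, pid = _panel_data(seed=4)
        fe1 = fit_fe_within(y, X, pid, pid)
        shift = np.random.default_rng(0).normal(0, 3, len(np.unique(pid)))[pid]
        X2 = X.copy()
        X2[:, 1] += shift
        fe2 = fit_fe_within(y, X2, pid, pid)
        assert abs(fe1.coef("x1") - fe2.coef("x1")) < 1e-10

    def test_removes_time_constant_confounding(self):
        biases_ols, biases_fe = [], []
        for r in range(50):
            y, X, pid = _panel_data(n_persons=80, t=4, seed=100 + r,
                                    confounded=True)
            biases_ols.append(fit_lpm(y, X, pid).coef("x1") - 0.5)
            biases_fe.append(fit_fe_within(y, X, pid, pid).coef("x1") - 0.5)
        assert abs(np.mean(biases_ols)) > 0.3  # pooled OLS clearly biased
        assert abs(np.mean(biases_fe)) < 0.05

    def test_all_time_constant_error(self):
        pid = np.repeat(np.arange(10), 3)
        X = np.column_stack([np.ones(30), np.arange(10).repeat(3)])
        with pytest.raises(InvalidParameterError):
            fit_fe_within(np.random.default_rng(0).normal(size=30), X, pid, pid)


def _iv_data(n=4000, seed=0, n_instruments=1, pi_strength=0.8):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    Z = rng.normal(size=(n, n_instruments))
    v = rng.normal(size=n)
    s = Z @ np.full(n_instruments, pi_strength) + X[:, 1] * 0.3 + v
    y = 0.7 * s + X[:, 1] * 0.5 + v * 0.8 + rng.normal(size=n)
    return y, s, X, Z


class TestLIML:
    def test_just_identified_equals_iv_closed_form(self):
        y, s, X, Z = _iv_data(seed=5)
        fit = fit_liml(y, s, X, Z, np.arange(len(y)))
        W = np.column_stack([s, X])
        instruments = np.column_stack([Z, X])
        beta_iv = np.linalg.solve(instruments.T @ W, instruments.T @ y)
        assert abs(fit.coef("attendance") - beta_iv[0]) < 1e-8
        assert fit.kappa == pytest.approx(1.0, abs=1e-8)

    def test_kappa_at_least_one(self):
        for seed in range(5):
            y, s, X, Z = _iv_data(seed=seed, n_instruments=3, pi_strength=0.3)
            fit = fit_liml(y, s, X, Z, np.arange(len(y)))
            assert fit.kappa >= 1.0 - 1e-10

    def test_strong_instrument_coverage(self):
        hits = 0
        reps = 50
        for r in range(reps):
            y, s, X, Z = _iv_data(n=2000, seed=200 + r, n_instruments=2)
            fit = fit_liml(y, s, X, Z, np.arange(len(y)))
            hits += abs(fit.coef("attendance") - 0.7) <= 2 * fit.se("attendance")
        assert hits / reps >= 0.90

    def test_no_instruments_rejected(self):
        y, s, X, _ = _iv_data(n=100, seed=1)
        with pytest.raises(InvalidParameterError):
            fit_liml(y, s, X, np.empty((100, 0)), np.arange(100))


class TestDeltaStar:
    def _fits(self, b0, r0, b1, r1):
        def mk(b, r2):
            return type("F", (), {
                "coef": lambda self, name: b, "r_squared": r2})()
        return mk(b0, r0), mk(b1, r1)

    def test_target_already_met(self):
        un, con = self._fits(-0.5, 0.1, 0.0, 0.3)
        assert delta_star(un, con).delta_star == 0.0

    def test_perfect_stability_unbounded(self):
        un, con = self._fits(-0.5, 0.1, -0.5, 0.3)
        assert delta_star(un, con).unbounded

    def test_matches_root_search_oracle(self):
        b0, r0, b1, r1, rmax = -0.030, 0.02, -0.014, 0.08, 0.15
        un, con = self._fits(b0, r0, b1, r1)
        result = delta_star(un, con, r_max=rmax)

        def adjusted(d):
            return b1 - d * (b0 - b1) * (rmax - r1) / (r1 - r0)

        root = brentq(adjusted, -100, 100, xtol=1e-12)
        assert abs(result.delta_star - root) < 1e-6

    def test_r2_ordering_enforced(self):
        un, con = self._fits(-0.5, 0.3, -0.2, 0.2)
        with pytest.raises(InvalidParameterError):
            delta_star(un, con)
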