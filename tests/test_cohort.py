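"""Generator: error structure, determinism, calibration, monotonicity."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from schoolhiv.biprobit import cell_probabilities
from schoolhiv.cohort import (
    default_config,
    draw_correlated_errors,
    generate_cohort,
    recovery_config,
    simulate_outcome_cells,
)
from schoolhiv.exceptions import InvalidParameterError
from schoolhiv.panel import panel_from_cohort


class TestCorrelatedErrors:
    @pytest.mark.parametrize("rho", [0.0, 0.5, -0.8])
    def test_sample_correlation_matches_target(self, rho):
        n = 100_000
        e = draw_correlated_errors(n, rho, seed=7)
        r = np.corrcoef(e[:, 0], e[:, 1])[0, 1]
        # MC SE of a sample correlation is ~ (1 - rho^2)/sqrt(n)
        assert abs(r - rho) < 3.0 * (1.0 - rho**2) / np.sqrt(n)

    def test_margins_standard_normal(self):
        e = draw_correlated_errors(50_000, 0.0, seed=3)
        for col in e.T:
            assert stats.kstest(col, "norm").pvalue > 0.01

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_invalid_rho_rejected(self, rho):
        with pytest.raises(InvalidParameterError):
            draw_correlated_errors(10, rho, seed=0)


class TestOutcomeCells:
    def test_symmetric_independent_quarters(self):
        cells = simulate_outcome_cells(0.0, 0.0, 0.0, 0.0, n=200_000, seed=5)
        for v in cells.values():
            assert abs(v - 0.25) < 0.005

    def test_matches_orthant_probabilities(self):
        cells = simulate_outcome_cells(0.0, 0.0, 0.0, 0.5, n=400_000, seed=9)
        p11, p10, p01, p00 = cell_probabilities(0.0, 0.0, 0.0, 0.5)
        assert abs(cells[(1, 1)] - float(p11)) < 0.004
        assert abs(cells[(0, 0)] - float(p00)) < 0.004

    def test_degenerate_large_index(self):
        cells = simulate_outcome_cells(50.0, 0.0, 0.0, 0.0, n=10_000, seed=1)
        assert cells[(0, 0)] == 0.0 and cells[(0, 1)] == 0.0


class TestGenerateCohort:
    def test_reproducible_bit_identical(self):
        cfg = default_config(n_individuals=400, seed=13)
        a = generate_cohort(cfg)
        b = generate_cohort(default_config(n_individuals=400, seed=13))
        pd.testing.assert_frame_equal(a.persons, b.persons)
        pd.testing.assert_frame_equal(a.person_years, b.person_years)
        pd.testing.assert_frame_equal(a.observed_tests, b.observed_tests)

    def test_full_testing_leaves_no_missing_incidence(self):
        cfg = default_config(n_individuals=600, seed=2, test_prob=1.0)
        panel, log = panel_from_cohort(generate_cohort(cfg))
        assert log["rows_uncertain_incidence"] == 0

    def test_test_history_consistent_with_seroconversion(self, small_cohort):
        merged = small_cohort.observed_tests.merge(
            small_cohort.persons[["person_id", "seroconversion_year"]],
            on="person_id")
        sero = merged["seroconversion_year"]
        neg = merged[merged["result"] == "neg"]
        pos = merged[merged["result"] == "pos"]
        assert not (neg["year"] >= sero[neg.index]).any()
        assert not (pos["year"] < sero[pos.index]).any()

    def test_error_pairs_track_config_rho(self):
        cfg = recovery_config(4000, seed=21, rho=-0.24)
        coh = generate_cohort(cfg)
        r = np.corrcoef(coh.person_years["latent_u"],
                        coh.person_years["latent_eps"])[0, 1]
        assert abs(r - (-0.24)) < 0.03

    def test_null_model_independence(self):
        """beta = 0, rho = 0, no a_i, flat hazard: s and y independent."""
        from schoolhiv.cohort import EquationCoefficients

        cfg = recovery_config(4000, seed=17, rho=0.0, beta=0.0)
        cfg.hiv_eq = EquationCoefficients(
            intercept=-1.9, age={a: 0.0 for a in range(14, 25)},
            year={t: 0.0 for t in cfg.years}, urban=0.0, peri_urban=0.0,
            dist_primary=0.0, dist_secondary=0.0)
        panel, _ = panel_from_cohort(generate_cohort(cfg))
        table = pd.crosstab(panel["attendance"], panel["incidence"])
        assert stats.chi2_contingency(table).pvalue > 0.01

    def test_instrument_monotonicity_common_random_numbers(self):
        base = default_config(n_individuals=2000, seed=5)
        boosted = default_config(n_individuals=2000, seed=5, gamma_near7=1.5)
        share = {}
        for tag, cfg in [("base", base), ("boost", boosted)]:
            coh = generate_cohort(cfg)
            py = coh.person_years.merge(coh.persons[["person_id", "dist_school"]],
                                        on="person_id")
            near = py[py["dist_school"] < 7.0]
            share[tag] = near["attendance"].mean()
        assert share["boost"] > share["base"]

    def test_invalid_configs_rejected(self):
        with pytest.raises(InvalidParameterError):
            default_config(n_individuals=100, rho=1.2)
        with pytest.raises(InvalidParameterError):
            default_config(n_individuals=100, geography_shares=(0.5, 0.2, 0.2))
        with pytest.raises(InvalidParameterError):
            default_config(n_individuals=100, years=(2005, 2007, 2008))
        with pytest.raises(InvalidParameterError):
            default_config(n_individuals=100, reentry_prob=0.2, dropout_prob=None)


class TestCalibration:
    def test_default_calibration_tracks_study_rates(self):
        """Attendance ~77.6%, incidence ~2.66%, re-entry ~23.9%, drop-out ~12.0%."""
        stats_ = []
        for seed in range(20):
            coh = generate_cohort(default_config(n_individuals=1200, seed=seed))
            panel, _ = panel_from_cohort(coh)
            re, dr = coh.measured_transition_rates()
            stats_.append((panel["attendance"].mean(), panel["incidence"].mean(),
                           re, dr))
        att, inc, re, dr = np.mean(stats_, axis=0)
        assert abs(att - 0.7759) < 0.02
        assert abs(inc - 0.0266) < 0.006
        assert abs(re - 0.2392) < 0.02
        assert abs(dr - 0.1195) < 0.02
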