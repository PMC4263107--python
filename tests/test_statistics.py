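"""GOF band, residual normality, identifiability, linearized statistics,
Monte Carlo / profile CIs and the normalized precision function."""

import numpy as np
import pytest
from scipy import stats as sps

from emuflux import statistics as st
from emuflux.statistics import _mc1_bounds, _mc2_bounds


class TestChi2Band:
    def test_printed_lower_quantile_at_30_dof(self):
        g = st.chi2_gof(20.0, W=45, p=15, alpha=0.05)
        assert g["dof"] == 30
        assert round(g["lower"], 2) == 16.79

    def test_band_edges_fail_strictly(self):
        lo = sps.chi2.ppf(0.025, 10)
        g = st.chi2_gof(lo, W=12, p=2, alpha=0.05)
        assert not g["accept"]

    def test_becker_fit_inside_band(self):
        g = st.chi2_gof(18.2, W=36, p=15, alpha=0.05)
        assert g["dof"] == 21 and g["accept"]

    @pytest.mark.parametrize("alpha", [0.05, 0.32])
    def test_both_significance_levels_supported(self, alpha):
        g = st.chi2_gof(25.0, W=45, p=15, alpha=alpha)
        assert g["lower"] == pytest.approx(sps.chi2.ppf(alpha / 2, 30))

    def test_unidentifiable_problem_refused(self):
        with pytest.raises(ValueError, match="identifiable"):
            st.chi2_gof(1.0, W=10, p=10)


class TestResidualNormality:
    def test_standard_normal_sample_not_rejected(self):
        r = np.random.default_rng(0).normal(size=50)
        out = st.residual_normality(r)
        assert not out["rejected"]

    def test_all_zero_residuals_flag_overfit(self):
        out = st.residual_normality(np.zeros(30))
        assert out["suspicious_small"] and out["rejected"]

    def test_injected_extremes_flagged_and_rejected(self):
        r = np.concatenate([np.random.default_rng(1).normal(size=30), [4.5, -5.0, 6.0]])
        out = st.residual_normality(r)
        assert len(out["extreme"]) == 3
        assert out["rejected"]


class TestIdentifiability:
    def test_full_rank_matrix_has_empty_null_space(self):
        J = np.random.default_rng(2).normal(size=(20, 5))
        assert st.identifiability(J).shape[1] == 0

    def test_duplicate_columns_yield_known_direction(self):
        J = np.random.default_rng(3).normal(size=(20, 3))
        J[:, 1] = J[:, 0]
        ns = st.identifiability(J)
        assert ns.shape[1] == 1
        v = ns[:, 0] * np.sign(ns[0, 0])
        np.testing.assert_allclose(v, [1, -1, 0] / np.sqrt(2), atol=1e-10)


class _LinearModel:
    """Duck-typed linear-Gaussian estimation problem with closed-form stats."""

    def __init__(self, X, y, sigma, seed=0):
        self.X, self.y, self.sigma = X, y, sigma

        class P:
            pass

        self.partition = P()
        self.partition.Z = np.eye(X.shape[1])
        self.partition.flux_ids = [f"b{i}" for i in range(X.shape[1])]

    def residuals(self, theta):
        return (self.X @ np.asarray(theta) - self.y) / self.sigma


class TestLinearizedStats:
    def test_linear_gaussian_closed_form(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 3))
        sigma = rng.uniform(0.5, 2.0, size=30)
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.normal(scale=sigma)
        model = _LinearModel(X, y, sigma)
        ls = st.linearized_stats(model, np.zeros(3))
        W = np.diag(1 / sigma**2)
        expected = np.linalg.inv(X.T @ W @ X)
        np.testing.assert_allclose(ls.covariance_theta, expected, rtol=1e-4)

    def test_cm_unit_row_for_exclusively_determined_parameter(self):
        # parameter 0 measured directly and only by measurement 0
        X = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0]])
        model = _LinearModel(X, np.zeros(3), np.ones(3))
        ls = st.linearized_stats(model, np.zeros(2))
        np.testing.assert_allclose(ls.contribution_matrix[0], [1.0, 0.0, 0.0], atol=1e-10)
        np.testing.assert_allclose(ls.contribution_matrix.sum(axis=1), 1.0, atol=1e-6)
        assert (ls.contribution_matrix >= -1e-12).all()

    def test_inflating_a_sigma_raises_its_contribution(self):
        X = np.array([[1.0, 0.5], [0.6, 1.0], [0.8, 0.2]])
        base = st.linearized_stats(_LinearModel(X, np.zeros(3), np.ones(3)), np.zeros(2))
        # measurement 2 ten times noisier: its *weighted* row shrinks, so the
        # relative variance share of the remaining measurements grows
        noisy = st.linearized_stats(
            _LinearModel(X, np.zeros(3), np.array([1.0, 1.0, 10.0])), np.zeros(2)
        )
        assert noisy.contribution_matrix[0, 2] < base.contribution_matrix[0, 2]


class TestMonteCarloBounds:
    def test_order_statistic_rule_on_presorted_estimates(self):
        est = np.arange(1.0, 501.0)
        lb, ub = _mc1_bounds(est, 0.95)
        assert (lb, ub) == (13.0, 488.0)  # 13th and 488th order statistics
        lb68, ub68 = _mc1_bounds(est, 0.68)
        d = int(np.floor(500 * 0.16))
        assert (lb68, ub68) == (est[d], est[499 - d])

    def test_symmetric_gaussian_strategies_agree(self):
        est = np.sort(np.random.default_rng(5).normal(10.0, 2.0, size=5000))
        l1, u1 = _mc1_bounds(est, 0.95)
        l2, u2 = _mc2_bounds(est, 0.95)
        assert abs(l1 - l2) < 0.15 and abs(u1 - u2) < 0.15

    def test_outliers_perturb_mean_varianced_not_discarding(self):
        base = np.random.default_rng(6).normal(10.0, 1.0, size=500)
        spiked = np.concatenate([base[:-5], [1e3] * 5])
        l1a, u1a = _mc1_bounds(np.sort(base), 0.95)
        l1b, u1b = _mc1_bounds(np.sort(spiked), 0.95)
        assert abs(u1b - u1a) < 0.5  # discarding barely moves
        _, u2a = _mc2_bounds(base, 0.95)
        _, u2b = _mc2_bounds(spiked, 0.95)
        assert u2b > u2a + 50  # mean-varianced blows up


class _OneParamModel:
    """Quadratic 1-parameter problem: direct measurements of θ."""

    def __init__(self, y, sigma):
        self.y, self.sigma = np.asarray(y, float), sigma

        class P:
            pass

        self.partition = P()
        self.partition.Z = np.ones((1, 1))
        self.partition.flux_ids = ["theta"]
        self.partition.lower = np.array([0.0])
        self.partition.upper = np.array([np.inf])

    def residuals(self, theta):
        return (np.atleast_1d(theta)[0] - self.y) / self.sigma

    def xi(self, theta):
        r = self.residuals(theta)
        return float(r @ r)


class TestNonlinearCI:
    def test_quadratic_interval_matches_analytic(self):
        y = np.array([9.5, 10.5, 10.0, 10.2])
        model = _OneParamModel(y, 0.5)
        theta_hat = np.array([y.mean()])
        out = st.nonlinear_ci(model, theta_hat, "theta", gamma=0.95)
        se = 0.5 / np.sqrt(len(y))
        z = np.sqrt(sps.chi2.ppf(0.95, 1))
        assert out["LB"] == pytest.approx(y.mean() - z * se, abs=2e-3)
        assert out["UB"] == pytest.approx(y.mean() + z * se, abs=2e-3)
        assert out["reliable"]

    def test_nesting_violation_detected(self):
        ci68 = {"LB": 1.0, "UB": 5.0}
        ci95 = {"LB": 2.0, "UB": 4.0}
        assert not st.check_nesting(ci68, ci95)
        assert st.check_nesting({"LB": 2.5, "UB": 3.5}, ci95)


class TestEta:
    def test_unit_precision_at_zero_width(self):
        assert st.eta(10.0, 0.0, 100.0) == 1.0

    def test_zero_precision_beyond_scaled_denominator(self):
        assert st.eta(1.0, 50.0, 100.0, beta=0.1) == 0.0

    def test_hand_substitution(self):
        assert st.eta(50.0, 30.0, 100.0, beta=0.1) == pytest.approx(0.5)

    def test_sum_over_fluxes(self):
        s = st.sum_eta([50.0, 10.0], [30.0, 0.0], 100.0, beta=0.1)
        assert s == pytest.approx(0.5 + 1.0)
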