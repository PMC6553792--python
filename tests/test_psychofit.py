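"""Weibull psychometric machinery and factor-curve summaries."""

import numpy as np
import pytest

from coneobserver import (
    ALPHA_2AFC,
    fit_factor_curve,
    fit_threshold,
    required_factor_change,
    weibull,
)
from coneobserver.psychofit import weibull_k


class TestWeibullForm:
    def test_threshold_criterion_alpha(self):
        assert ALPHA_2AFC == pytest.approx(0.5 ** (1 / 3))
        assert weibull(0.03, t=0.03) == pytest.approx(ALPHA_2AFC, abs=1e-12)

    @pytest.mark.parametrize("g,beta,alpha", [(0.5, 3.0, ALPHA_2AFC), (0.5, 2.0, 0.75), (0.25, 3.5, 0.6)])
    def test_identity_holds_for_any_parameters(self, g, beta, alpha):
        t = 0.042
        y = 1 - (1 - g) * np.exp(-((weibull_k(beta, g, alpha) * t / t) ** beta))
        assert y == pytest.approx(alpha, abs=1e-12)
        assert weibull(t, t, beta, g, alpha) == pytest.approx(alpha, abs=1e-12)

    def test_chance_at_zero_and_saturation(self):
        assert weibull(0.0, 0.03) == pytest.approx(0.5)
        assert weibull(5.0, 0.03) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            weibull(0.1, t=0.0)


class TestThresholdFit:
    def test_noiseless_recovery(self):
        x = np.geomspace(0.003, 0.1, 8)
        y = weibull(x, t=0.03)
        fit = fit_threshold(x, y)
        assert fit.t == pytest.approx(0.03, abs=1e-6)

    def test_binomial_recovery_within_10pct(self):
        """400-trial binomial data at 15 levels recover t=0.027 within 10%."""
        x = np.geomspace(0.0005, 0.10, 15)
        t_true = 0.027
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.binomial(400, weibull(x, t_true)) / 400.0
            errs.append(abs(fit_threshold(x, y).t - t_true) / t_true)
        assert np.median(errs) < 0.10
        assert np.mean(np.asarray(errs) < 0.10) >= 0.9

    def test_chance_data_flagged_not_a_number(self):
        x = np.geomspace(0.001, 0.1, 8)
        fit = fit_threshold(x, np.full(8, 0.5))
        assert not fit.identifiable
        assert np.isnan(fit.t)

    def test_scale_equivariance(self):
        x = np.geomspace(0.003, 0.1, 10)
        rng = np.random.default_rng(5)
        y = np.clip(weibull(x, 0.02) + rng.normal(0, 0.01, len(x)), 0, 1)
        t1 = fit_threshold(x, y).t
        t2 = fit_threshold(3.0 * x, y).t
        assert t2 == pytest.approx(3.0 * t1, rel=1e-3)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_threshold([0.01, 0.02, 0.04], [0.5, 0.6, 0.9])

    def test_bootstrap_ci_covers_generating_threshold(self):
        """Percentile-bootstrap 95% CIs contain the true t in >= 90% of replicates."""
        x = np.geomspace(0.002, 0.10, 10)
        t_true = 0.025
        covered = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            y = rng.binomial(200, weibull(x, t_true)) / 200.0
            boots = []
            for _ in range(60):
                yb = rng.binomial(200, np.clip(y, 0, 1)) / 200.0
                f = fit_threshold(x, yb)
                if f.identifiable:
                    boots.append(f.t)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            covered += lo <= t_true <= hi
        assert covered >= 18


class TestFactorCurves:
    def test_collinear_points_give_r2_one(self):
        f = fit_factor_curve([0, 1, 2, 3], [1.0, 1.5, 2.0, 2.5], "linear")
        assert f.r_squared == pytest.approx(1.0)
        assert f.slope == pytest.approx(0.5)

    def test_quadratic_recovers_coefficients(self):
        x = np.linspace(0, 1, 11)
        th = 2.0 - 3.0 * x + 3.0 * x**2
        f = fit_factor_curve(x, th, "quadratic")
        assert np.allclose(f.coefficients, [3.0, -3.0, 2.0], atol=1e-9)
        assert f.r_squared == pytest.approx(1.0)

    def test_log_linear_straight_in_log_density(self):
        d = np.geomspace(466, 22500, 6)
        th = 5.0 - 1.285 * np.log10(d)
        f = fit_factor_curve(d, th, "log-linear")
        assert f.r_squared == pytest.approx(1.0)
        assert f.slope == pytest.approx(-1.285, abs=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_factor_curve([1, 2], [0.1, 0.2], "quadratic")


class TestRequiredFactorChange:
    def test_linear_inversion_gives_about_7_diopters(self):
        """With the fitted sensitivity of threshold to defocus (~0.21 pp/D),
        a 1.5-pp rise takes ~7 D."""
        dio = np.array([0.0, 1.54, 3.08, 4.62, 6.16])
        th = 2.7 + 0.214 * dio
        f = fit_factor_curve(dio, th, "linear")
        assert required_factor_change(f, 1.5) == pytest.approx(7.0, rel=0.02)

    def test_log_linear_inversion_gives_about_6_fold(self):
        d = np.geomspace(466, 22500, 8)
        th = 7.0 - 1.285 * np.log10(d)
        f = fit_factor_curve(d, th, "log-linear")
        assert required_factor_change(f, 1.0) == pytest.approx(6.0, rel=0.01)

    def test_zero_delta_is_identity(self):
        f = fit_factor_curve([0, 1, 2], [1.0, 2.0, 3.0], "linear")
        assert required_factor_change(f, 0.0) == 0.0
        flog = fit_factor_curve([100, 1000, 10000], [3.0, 2.0, 1.0], "log-linear")
        assert required_factor_change(flog, 0.0) == pytest.approx(1.0)

    def test_quadratic_rejected(self):
        f = fit_factor_curve([0, 0.5, 1], [1.0, 0.5, 1.0], "quadratic")
        with pytest.raises(ValueError):
            required_factor_change(f, 1.0)
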