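"""Scaling-model fits, information criteria and model selection."""

import math

import numpy as np
import pytest

from corolla.aggregate import FlowerSummary
from corolla.geometry import PetalRecord
from corolla.models import (bootstrap_ci, compute_aic, compute_rmse,
                            fit_montgomery, fit_total_area_model,
                            percent_error, predict_area, predict_total_area,
                            select_model)
from corolla.synthetic import SpeciesConfig, SyntheticConfig, generate_dataset

from conftest import exact_me_petals


def flowers_from_loglog(x, y, species="sp"):
    """Flower summaries with ln(L_KS W_KS) = x and ln(A_T) = y."""
    return [FlowerSummary(species, f"f{i}", 5, math.exp(yi), math.exp(xi), 1.0)
            for i, (xi, yi) in enumerate(zip(x, y))]


class TestMontgomery:
    def test_zero_noise_recovers_k(self):
        fit = fit_montgomery(exact_me_petals(0.7, 50))
        assert fit.k_hat == pytest.approx(0.7, rel=1e-12)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)
        assert fit.slope == 1.0
        assert math.isnan(fit.aic)  # degenerate likelihood at rss = 0

    def test_hand_computed_residuals(self):
        resid = [0.1, -0.1, 0.0, 0.2, -0.2]
        petals = []
        rng = np.random.default_rng(1)
        for i, e in enumerate(resid):
            L, W = rng.uniform(1, 2, 2)
            petals.append(PetalRecord("sp", f"f{i}", "p1",
                                      0.6 * L * W * math.exp(e), L, W))
        fit = fit_montgomery(petals)
        assert fit.intercept == pytest.approx(math.log(0.6), abs=1e-12)
        assert fit.rmse == pytest.approx(math.sqrt(0.02), rel=1e-12)

    def test_nonpositive_rejected_before_transform(self):
        good = exact_me_petals(0.7, 5)
        bad = good + [object.__new__(PetalRecord)]
        object.__setattr__(bad[-1], "species", "sp")
        object.__setattr__(bad[-1], "flower_id", "f")
        object.__setattr__(bad[-1], "petal_id", "p")
        object.__setattr__(bad[-1], "A", -1.0)
        object.__setattr__(bad[-1], "L", 1.0)
        object.__setattr__(bad[-1], "W", 1.0)
        with pytest.raises(ValueError, match="positive"):
            fit_montgomery(bad)

    def test_needs_two_petals(self):
        with pytest.raises(ValueError):
            fit_montgomery(exact_me_petals(0.7, 1))

    def test_unit_change_leaves_k_dimensionless(self):
        cm = exact_me_petals(0.64, 40, seed=2)
        mm = [PetalRecord(p.species, p.flower_id, p.petal_id,
                          p.A * 100.0, p.L * 10.0, p.W * 10.0) for p in cm]
        assert fit_montgomery(mm).k_hat == pytest.approx(
            fit_montgomery(cm).k_hat, rel=1e-12)

    def test_log_base_invariance(self):
        rng = np.random.default_rng(8)
        petals = [PetalRecord("sp", f"f{i}", "p",
                              0.7 * L * W * math.exp(rng.normal(0, 0.05)),
                              L, W)
                  for i, (L, W) in enumerate(zip(rng.uniform(1, 2, 60),
                                                 rng.uniform(0.5, 1, 60)))]
        nat = fit_montgomery(petals)
        b10 = fit_montgomery(petals, log_base=10.0)
        assert b10.k_hat == pytest.approx(nat.k_hat, rel=1e-12)
        assert b10.r == pytest.approx(nat.r, rel=1e-12)
        assert b10.rmse == pytest.approx(nat.rmse, rel=1e-12)  # natural-log units
        assert b10.intercept == pytest.approx(nat.intercept / math.log(10),
                                              rel=1e-12)


class TestPredictions:
    def test_montgomery_prediction(self):
        fit = fit_montgomery(exact_me_petals(0.5, 10))
        assert predict_area(fit, 2.0, 1.0) == pytest.approx(1.0)

    def test_identity_when_k_is_one(self):
        fit = fit_montgomery(exact_me_petals(1.0, 10))
        L, W = np.array([1.3, 2.0]), np.array([0.7, 1.1])
        np.testing.assert_allclose(predict_area(fit, L, W), L * W)

    def test_zero_noise_predictions_match_generated_areas(self):
        cfg = SyntheticConfig(species=(SpeciesConfig(
            name="s", n_flowers=10, petal_count=(5, 6), length_mean=1.5,
            length_sd=0.15, ratio_mean=0.7, ratio_sd=0.03, p1=1.0, p2=0.8,
            sigma_log_area=0.0),), seed=11, n_vertices=128)
        ds = generate_dataset(cfg)
        fit = fit_montgomery(ds.petals)
        for p, a_true in zip(ds.petals, ds.true_areas):
            assert predict_area(fit, p.L, p.W) == pytest.approx(
                a_true, rel=1e-10)

    def test_wrong_model_type_rejected(self):
        flowers = flowers_from_loglog(np.linspace(0, 1, 5),
                                      np.linspace(-0.5, 0.5, 5))
        fit = fit_total_area_model(flowers, "MKSE")
        with pytest.raises(ValueError, match="ME"):
            predict_area(fit, 1.0, 1.0)
        assert predict_total_area(fit, 2.0, 3.0) == pytest.approx(
            fit.k_hat * 6.0)


class TestTotalAreaModels:
    def test_zero_noise_mkse_and_nested_ple_agree(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0.5, 2.0, 30)
        flowers = [FlowerSummary("sp", f"f{i}", 5, 0.8 * lks * wks, lks, wks)
                   for i, (lks, wks) in enumerate(zip(x, x + 1))]
        mkse = fit_total_area_model(flowers, "MKSE")
        ple = fit_total_area_model(flowers, "PLE")
        assert mkse.k_hat == pytest.approx(0.8, rel=1e-12)
        assert mkse.rmse == pytest.approx(0.0, abs=1e-12)
        assert ple.slope == pytest.approx(1.0, rel=1e-9)

    def test_ple_alpha_recovery_simulation(self):
        # closed-form OLS is the oracle: over 200 seeds the mean slope
        # estimate stays within 3 standard errors of the truth
        alpha, gamma, sigma, n = 0.85, -0.3, 0.03, 60
        est = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.0, 2.0, n)
            y = gamma + alpha * x + rng.normal(0, sigma, n)
            fit = fit_total_area_model(flowers_from_loglog(x, y), "PLE")
            est.append(fit.slope)
        se_mean = np.std(est, ddof=1) / math.sqrt(len(est))
        assert abs(np.mean(est) - alpha) <= 3 * se_mean

    def test_needs_three_flowers(self):
        flowers = flowers_from_loglog([0.0, 1.0], [0.0, 0.9])
        with pytest.raises(ValueError):
            fit_total_area_model(flowers, "PLE")

    def test_ple_never_fits_worse_than_mkse(self):
        # the PLE nests the MKSE, so its least-squares RMSE cannot exceed
        # the MKSE's on any dataset
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = rng.integers(5, 40)
            x = rng.uniform(-1, 2, n)
            y = rng.uniform(-1, 2, n)
            flowers = flowers_from_loglog(x, y)
            mkse = fit_total_area_model(flowers, "MKSE")
            ple = fit_total_area_model(flowers, "PLE")
            assert ple.rmse <= mkse.rmse + 1e-12
            assert percent_error(mkse.rmse, ple.rmse) >= -1e-9


class TestErrorMetrics:
    def test_rmse_identical_vectors(self):
        assert compute_rmse(np.ones(4), np.ones(4)) == 0.0

    def test_rmse_hand_arithmetic(self):
        assert compute_rmse(np.array([0.3, -0.4]), np.zeros(2)) == \
            pytest.approx(math.sqrt(0.125))

    def test_rmse_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_rmse(np.ones(3), np.ones(4))

    def test_aic_loglik_zero_construction(self):
        # rss/n = 1/(2 pi e) makes the Gaussian max log-likelihood zero,
        # so AIC reduces to 2p
        n = 10
        rss = n / (2 * math.pi * math.e)
        assert compute_aic(n, rss, 1) == pytest.approx(4.0, abs=1e-10)
        assert compute_aic(n, rss, 2) == pytest.approx(6.0, abs=1e-10)

    def test_aic_zero_rss_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            compute_aic(10, 0.0, 1)

    def test_percent_error_trivia(self):
        assert percent_error(0.5, 0.5) == 0.0
        assert percent_error(0.5, 0.0) == 100.0
        with pytest.raises(ValueError):
            percent_error(0.0, 0.1)


class TestSelectModel:
    def make_pair(self, noise, seed=0, curvature=0.0):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 2, 40)
        y = 0.9 * x - 0.2 + curvature * (x - 1) ** 2 + rng.normal(0, noise, 40)
        flowers = flowers_from_loglog(x, y)
        return (fit_total_area_model(flowers, "MKSE"),
                fit_total_area_model(flowers, "PLE"))

    def test_equal_rmse_prefers_simple(self):
        # residuals orthogonal to the predictor: the free PLE slope stays
        # exactly 1, both models share one RMSE, PE = 0 -> simpler wins
        x = np.array([0.0, 1.0, 2.0])
        y = x + np.array([0.1, -0.2, 0.1])
        flowers = flowers_from_loglog(x, y)
        mkse = fit_total_area_model(flowers, "MKSE")
        ple = fit_total_area_model(flowers, "PLE")
        cmp_ = select_model(mkse, ple)
        assert cmp_.pe == pytest.approx(0.0, abs=1e-9)
        assert cmp_.preferred == "MKSE"

    def test_strong_anisometry_selects_ple(self):
        mkse, ple = self.make_pair(noise=0.02, curvature=0.0)
        cmp_ = select_model(mkse, ple)
        assert cmp_.pe > 5.0  # slope 0.9 far from 1 at low noise
        assert cmp_.preferred == "PLE"

    def test_tie_at_threshold_prefers_simple(self):
        mkse, ple = self.make_pair(noise=0.05, seed=3)
        pe = percent_error(mkse.rmse, ple.rmse)
        cmp_ = select_model(mkse, ple, threshold=pe)
        assert cmp_.preferred == "MKSE"

    def test_mismatched_n_rejected(self):
        mkse, _ = self.make_pair(noise=0.05)
        other = fit_total_area_model(
            flowers_from_loglog(np.linspace(0, 1, 7),
                                np.linspace(0, 0.9, 7)), "PLE")
        with pytest.raises(ValueError, match="same data"):
            select_model(mkse, other)

    def test_rule_trace_reports_slope_ci(self):
        rng = np.random.default_rng(12)
        x = rng.uniform(0, 2, 50)
        y = 1.0 * x - 0.3 + rng.normal(0, 0.05, 50)
        flowers = flowers_from_loglog(x, y)
        mkse = fit_total_area_model(flowers, "MKSE")
        ple = fit_total_area_model(flowers, "PLE", B=200, seed=5)
        cmp_ = select_model(mkse, ple)
        assert "contains 1" in cmp_.rule_trace
        assert "PE" in cmp_.rule_trace


class TestBootstrap:
    def test_deterministic_under_seed(self):
        petals = exact_me_petals(0.7, 30)
        noisy = [PetalRecord(p.species, p.flower_id, p.petal_id,
                             p.A * math.exp(0.05 * ((-1) ** i)), p.L, p.W)
                 for i, p in enumerate(petals)]
        a = bootstrap_ci(noisy, "ME", B=100, seed=42)
        b = bootstrap_ci(noisy, "ME", B=100, seed=42)
        assert a == b

    def test_zero_noise_interval_collapses(self):
        ci = bootstrap_ci(exact_me_petals(0.7, 20), "ME", B=200, seed=1)
        lo, hi = ci["k"]
        assert lo == pytest.approx(0.7, rel=1e-12)
        assert hi == pytest.approx(0.7, rel=1e-12)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_ci(exact_me_petals(0.7, 20), "ME", B=10)

    def test_slope_fixed_for_isometric_models(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 2, 25)
        y = x - 0.3 + rng.normal(0, 0.05, 25)
        ci = bootstrap_ci(flowers_from_loglog(x, y), "MKSE", B=50, seed=3)
        assert ci["slope"] == (1.0, 1.0)

    def test_fit_attaches_ordered_intervals(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 2, 40)
        y = 0.9 * x - 0.2 + rng.normal(0, 0.05, 40)
        fit = fit_total_area_model(flowers_from_loglog(x, y), "PLE",
                                   B=300, seed=9)
        assert fit.ci_slope[0] <= fit.slope <= fit.ci_slope[1]
        assert fit.ci_k[0] <= fit.k_hat <= fit.ci_k[1]
        assert fit.B == 300 and fit.seed == 9
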