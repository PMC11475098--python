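"""Equivalent-noise fits, extrinsic variance, and additivity decomposition."""

import numpy as np
import pytest

import equivnoise as en
from equivnoise.equivalent_noise import (_quadratic_surface_minimum,
                                         extrinsic_variance_simulated)
from equivnoise.observer import ConditionSimulator
from equivnoise.stimulus import Condition


class TestDirectNoiseFit:
    def test_two_point_exact_algebra(self):
        fit = en.fit_noise_curve_direct([0.0, 1.0], [3e-4, 3e-4 + 5e-4])
        assert fit.sigma_i2 == pytest.approx(3e-4, rel=1e-6)
        assert fit.sigma_e02 == pytest.approx(5e-4, rel=1e-6)

    def test_flat_curve_is_pure_intrinsic(self):
        fit = en.fit_noise_curve_direct([0, 0.01, 0.1, 1.0], [4e-4] * 4)
        assert fit.sigma_i2 == pytest.approx(4e-4, rel=1e-6)
        assert fit.sigma_e02 <= 1e-6 * fit.sigma_i2

    def test_noisy_recovery_within_fifteen_percent(self):
        rng = np.random.default_rng(13)
        levels = np.array([0.0, 0.01, 0.03, 0.1, 0.3, 1.0])
        si2, se02 = 4e-4, 6e-4
        t2 = np.exp(np.log(si2 + levels * se02)
                    + rng.normal(0, 0.05, levels.size))
        fit = en.fit_noise_curve_direct(levels, t2)
        assert fit.sigma_i2 == pytest.approx(si2, rel=0.15)
        assert fit.sigma_e02 == pytest.approx(se02, rel=0.15)

    def test_ratio_is_equivalent_noise_level(self):
        fit = en.EquivalentNoiseFit(4e-4, 6e-4)
        assert fit.ratio == pytest.approx(1.5)

    def test_non_identifiable_rejected(self):
        with pytest.raises(ValueError, match="identifiable"):
            en.fit_noise_curve_direct([0.3, 0.3], [1e-4, 2e-4])


class TestExtrinsicVariance:
    def test_identical_images_give_zero(self, scene_models, rng):
        img = en.to_cone_image(
            en.render_scene(0.40, 0.0, 0.0, "chromatic", scene_models, rng))
        rf = en.ReceptiveField(en.stimulus.default_target_mask(), -0.1)
        assert en.extrinsic_variance(rf, [img] * 5) == pytest.approx(0.0, abs=1e-18)

    def test_quadratic_form_equals_response_variance(self, scene_models, rng):
        images = [en.to_cone_image(
            en.render_scene(0.40, 1.0, 0.0, "chromatic", scene_models, rng))
            for _ in range(300)]
        rf = en.ReceptiveField(en.stimulus.default_target_mask(), -0.08, 2.0)
        obs = en.LINRFObserver(rf, 0.0)
        responses = [en.respond(obs, img) for img in images]
        assert en.extrinsic_variance(rf, images) == pytest.approx(
            np.var(responses, ddof=1), rel=1e-9)

    def test_scales_linearly_in_covariance_scalar(self, scene_models):
        rng = np.random.default_rng(23)
        rf = en.ReceptiveField(en.stimulus.default_target_mask(), -0.05, 1.0)
        s2_levels = np.array([0.25, 0.5, 1.0])
        values = np.array([
            extrinsic_variance_simulated(
                ConditionSimulator(scene_models, Condition(s2, 0.0)), rf,
                30_000, rng)
            for s2 in s2_levels])
        # proportional within sampling error: v(s2)/s2 constant to ~5%
        normalized = values / s2_levels
        assert normalized.max() / normalized.min() < 1.08


class TestLightExtrapolation:
    def test_exact_exponential_recovered(self):
        deltas = np.array([0.05, 0.1, 0.2, 0.3])
        vals = 2e-4 * np.exp(3.0 * deltas)
        out = en.extrapolate_light_variance(deltas, vals)
        assert out == pytest.approx(2e-4 * np.exp(3.0), rel=1e-9)

    def test_noisy_recovery_is_centered_on_truth(self):
        # extrapolation to delta = 1 amplifies measurement noise, so check
        # the estimator's central tendency over replicates at 5% noise
        rng = np.random.default_rng(2)
        deltas = np.linspace(0.05, 0.3, 6)
        clean = 2e-4 * np.exp(3.0 * deltas)
        estimates = [
            en.extrapolate_light_variance(
                deltas, clean * np.exp(rng.normal(0, 0.05, 6)))
            for _ in range(300)]
        assert np.median(estimates) == pytest.approx(2e-4 * np.exp(3.0),
                                                     rel=0.10)

    def test_constant_values_returned_unchanged(self):
        out = en.extrapolate_light_variance([0.1, 0.2, 0.3], [5e-4] * 3)
        assert out == pytest.approx(5e-4, rel=1e-6)

    def test_delta_zero_excluded_and_errors(self):
        with pytest.raises(ValueError, match="three"):
            en.extrapolate_light_variance([0.0, 0.1, 0.2], [1e-4, 1e-4, 1e-4])
        with pytest.raises(ValueError, match="positive"):
            en.extrapolate_light_variance([0.1, 0.2, 0.3], [1e-4, -1e-4, 1e-4])


class TestQuadraticSurface:
    def test_exact_quadratic_vertex(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 40)
        b = rng.uniform(0, 1, 40)
        # z with minimum at (0.3, 0.6)
        z = 2 * (a - 0.3) ** 2 + 0.5 * (b - 0.6) ** 2 + 0.3 * (a - 0.3) * (b - 0.6) + 1
        vertex, ok, _ = _quadratic_surface_minimum(a, b, z, (0, 1), (0, 1))
        assert ok
        assert vertex[0] == pytest.approx(0.3, abs=1e-9)
        assert vertex[1] == pytest.approx(0.6, abs=1e-9)

    def test_indefinite_surface_reports_failure(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, 40)
        b = rng.uniform(0, 1, 40)
        z = -(a - 0.5) ** 2 + (b - 0.5) ** 2  # saddle
        vertex, ok, _ = _quadratic_surface_minimum(a, b, z, (0, 1), (0, 1))
        assert not ok and vertex is None


class TestSimulationFitStructure:
    def test_small_grid_returns_valid_fit(self, scene_models):
        rng = np.random.default_rng(5)
        factory = lambda s2: ConditionSimulator(scene_models,
                                                Condition(float(s2), 0.0))
        fit = en.fit_linrf_by_simulation(
            measured_t=[0.020, 0.030], condition_levels=[0.0, 1.0],
            condition_factory=factory,
            sigma_i2_grid=[2e-4, 8e-4], vs_grid=[0.02, 0.08],
            rng=rng, n_per_level=200, n_calibration=200,
            reference_level=1.0, n_extrinsic=2000)
        assert fit.source == "simulation"
        assert fit.vs_hat <= 0
        assert fit.sigma_i2 >= 0 and fit.sigma_e02 >= 0
        assert len(fit.diagnostics["grid_mse"]) == 4


class TestDecomposition:
    def test_worked_example_with_reported_variances(self):
        # extrinsic variances 0.0015 (background) and 0.0017 (light);
        # simultaneous 0.0033 -> sum 0.0032, additivity gap 0.0001
        base = 4e-4
        d = en.decompose_variance({
            "none": base,
            "background": base + 0.0015,
            "light": base + 0.0017,
            "simultaneous": base + 0.0033,
        })
        assert d.sum_individual == pytest.approx(0.0032, abs=1e-12)
        assert d.additivity_gap == pytest.approx(0.0001, abs=1e-12)
        assert d.delta_t2["none"] == 0.0

    def test_equal_thresholds_give_zero_gap(self):
        d = en.decompose_variance({k: 5e-4 for k in
                                   ("none", "a", "b", "simultaneous")})
        assert d.sum_individual == 0.0
        assert d.additivity_gap == 0.0

    def test_requires_four_conditions(self):
        with pytest.raises(ValueError, match="four"):
            en.decompose_variance({"none": 1e-4, "a": 2e-4,
                                   "simultaneous": 3e-4})

    def test_frame_carries_gap(self):
        d = en.decompose_variance({"none": 1e-4, "a": 2e-4, "b": 3e-4,
                                   "simultaneous": 5e-4})
        frame = d.as_frame()
        assert frame.attrs["additivity_gap"] == pytest.approx(1e-4)
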