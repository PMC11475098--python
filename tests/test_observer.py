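"""LINRF observer: responses, calibration, 2AFC simulation."""

import dataclasses

import numpy as np
import pytest

import equivnoise as en
from equivnoise.equivalent_noise import extrinsic_variance_simulated
from equivnoise.observer import ConditionSimulator
from equivnoise.stimulus import Condition


def _cone(scene_models, rng, lrf=0.40, sigma2=0.0, delta=0.0):
    img = en.render_scene(lrf, sigma2, delta, "chromatic", scene_models, rng)
    return en.to_cone_image(img)


class TestRespond:
    def test_deterministic_without_intrinsic_noise(self, scene_models, rng):
        obs = en.LINRFObserver(en.ReceptiveField(
            en.stimulus.default_target_mask(), -0.1), 0.0)
        cone = _cone(scene_models, rng)
        assert en.respond(obs, cone) == en.respond(obs, cone)

    def test_intrinsic_noise_variance(self, scene_models, rng):
        obs = en.LINRFObserver(en.ReceptiveField(
            en.stimulus.default_target_mask(), -0.1), 0.05)
        cone = _cone(scene_models, rng)
        r = np.array([en.respond(obs, cone, rng) for _ in range(10_000)])
        assert r.var() == pytest.approx(0.05 ** 2, rel=0.05)

    def test_shape_mismatch_rejected(self, scene_models, rng):
        obs = en.LINRFObserver(en.ReceptiveField(
            en.stimulus.default_target_mask((7, 7)), -0.1), 0.0)
        with pytest.raises(ValueError, match="match"):
            en.respond(obs, _cone(scene_models, rng))

    def test_total_variance_decomposes(self, observer_factory):
        # response variance over scenes = sigma_i^2 + R' Sigma_e R
        obs, sim = observer_factory(Condition(1.0, 0.0), intrinsic_sd=0.02)
        rng = np.random.default_rng(17)
        r = sim.noise_free_responses(0.40, 20_000, rng, obs.rf)
        r = r + rng.normal(0, obs.intrinsic_sd, r.size)
        rtsr = extrinsic_variance_simulated(sim, obs.rf, 20_000, rng)
        assert r.var(ddof=1) == pytest.approx(0.02 ** 2 + rtsr, rel=0.05)


class TestCalibration:
    def test_response_difference_equals_delta_lrf(self, observer_factory):
        obs, sim = observer_factory(Condition(1.0, 0.0))
        rng = np.random.default_rng(3)
        hi = sim.mean_response(0.45, 20_000, rng, obs.rf)
        lo = sim.mean_response(0.35, 20_000, rng, obs.rf)
        assert hi - lo == pytest.approx(0.10, abs=0.002)

    def test_idempotent(self, observer_factory):
        obs, sim = observer_factory(Condition(0.0, 0.0))
        again = en.calibrate_rf_units(obs, sim, rng=np.random.default_rng(0))
        ratio = again.rf.calibration_scale / obs.rf.calibration_scale
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_zero_surround_no_variation_is_affine_identity(self, observer_factory):
        obs, sim = observer_factory(Condition(0.0, 0.0), surround=0.0)
        rng = np.random.default_rng(0)
        r35 = sim.noise_free_responses(0.35, 1, rng, obs.rf)[0]
        r45 = sim.noise_free_responses(0.45, 1, rng, obs.rf)[0]
        assert r45 - r35 == pytest.approx(0.10, abs=1e-9)

    def test_batch_path_matches_object_path(self, scene_models, observer_factory):
        obs, sim = observer_factory(Condition(0.0, 0.0), surround=-0.07,
                                    intrinsic_sd=0.0)
        rng = np.random.default_rng(2)
        cone = _cone(scene_models, rng)
        r_obj = en.respond(obs, cone)
        r_batch = sim.noise_free_responses(0.40, 1, rng, obs.rf)[0]
        assert r_obj == pytest.approx(r_batch, rel=1e-12)


class TestTrials:
    def test_larger_lrf_always_chosen_without_noise(self, scene_models,
                                                   observer_factory, rng):
        obs, _ = observer_factory(Condition(0.0, 0.0), intrinsic_sd=0.0)
        std = _cone(scene_models, rng, lrf=0.40)
        cmp_ = _cone(scene_models, rng, lrf=0.44)
        assert all(en.simulate_trial(obs, std, cmp_, rng) == "comparison"
                   for _ in range(20))

    def test_identical_images_choice_is_fair(self, scene_models,
                                             observer_factory, rng):
        obs, _ = observer_factory(Condition(0.0, 0.0), intrinsic_sd=0.02)
        img = _cone(scene_models, rng)
        n = 4000
        chose = sum(en.simulate_trial(obs, img, img, rng) == "comparison"
                    for _ in range(n))
        assert abs(chose / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_tie_broken_by_coin(self, scene_models, observer_factory, rng):
        obs, _ = observer_factory(Condition(0.0, 0.0), intrinsic_sd=0.0)
        img = _cone(scene_models, rng)
        picks = {en.simulate_trial(obs, img, img, rng) for _ in range(50)}
        assert picks == {"standard", "comparison"}


class TestSimulatePsychometric:
    def test_half_at_standard_level_and_monotone(self, observer_factory):
        obs, sim = observer_factory(Condition(0.3, 0.0), intrinsic_sd=0.02)
        table = en.simulate_psychometric(obs, sim, n_per_level=3000,
                                         rng=np.random.default_rng(9))
        p = table["n_comparison_chosen"] / table["n_trials"]
        at_standard = p[np.isclose(table["comparison_lrf"], 0.40)].iloc[0]
        assert abs(at_standard - 0.5) < 3 * np.sqrt(0.25 / 3000)
        # monotone after allowing binomial jitter
        slack = 3 * np.sqrt(0.25 / 3000)
        assert all(np.diff(p) > -2 * slack)

    def test_threshold_matches_total_noise_sd(self, observer_factory):
        # the fitted threshold recovers sqrt(sigma_i^2 + R' Sigma_e R)
        obs, sim = observer_factory(Condition(0.3, 0.0), intrinsic_sd=0.02)
        rng = np.random.default_rng(31)
        table = en.simulate_psychometric(obs, sim, n_per_level=8000, rng=rng)
        t = en.fit_psychometric(table).threshold
        rtsr = extrinsic_variance_simulated(sim, obs.rf, 30_000, rng)
        assert t == pytest.approx(np.sqrt(0.02 ** 2 + rtsr), rel=0.04)

    def test_levels_outside_range_rejected(self, observer_factory, rng):
        obs, sim = observer_factory()
        with pytest.raises(ValueError, match="0.35"):
            en.simulate_psychometric(obs, sim, levels=[0.3, 0.4, 0.5],
                                     n_per_level=10, rng=rng)


def test_observer_json_roundtrip(observer_factory, tmp_path):
    obs, _ = observer_factory(Condition(0.0, 0.0), surround=-0.08,
                              intrinsic_sd=0.03)
    path = tmp_path / "obs.json"
    obs.to_json(path)
    back = en.LINRFObserver.from_json(path)
    assert back.rf.surround_sensitivity == obs.rf.surround_sensitivity
    assert back.rf.calibration_scale == pytest.approx(obs.rf.calibration_scale)
    assert back.intrinsic_sd == obs.intrinsic_sd
    assert np.array_equal(back.rf.target_mask, obs.rf.target_mask)
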