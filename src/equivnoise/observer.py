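"""The linear-receptive-field (LINRF) model observer.

The observer weights the cone-response image with a centre-surround
receptive field: uniform sensitivity +1 on the target region and a uniform
non-positive surround sensitivity ``v_s`` elsewhere, with one identical
copy of the field per cone class.  The visual response is the dot product
of the field with the image plus a mean-zero Gaussian intrinsic noise; on
each two-interval trial the observer chooses the image with the larger
response as the one with the lighter target.

Because responses vary from image to image (extrinsic noise, through the
scene generators) and from trial to trial (intrinsic noise), the total
response variance is ``sigma_i^2 + R' Sigma_e R``, and with the 0.76/0.50
threshold convention the model's discrimination threshold T satisfies
``T^2 = sigma_i^2 + R' Sigma_e R`` (a d-prime of 1 in a two-interval task).

The receptive field carries a calibration scale that expresses responses
in LRF units: after calibration the mean noise-free response grows by
exactly Delta-LRF when the target LRF grows by Delta-LRF, so the intrinsic
noise standard deviation is directly comparable to thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .stimulus import (DEFAULT_INTEGRATION_MS, Condition, ConeImage,
                       SceneModels, StimulusImage, default_target_mask,
                       summed_cone_weight)
from .reflectance import sample_illuminant_scales, sample_reflectance_batch
from .synthetic import DEFAULT_LEVELS, STANDARD_LRF

__all__ = [
    "ReceptiveField",
    "LINRFObserver",
    "ConditionSimulator",
    "respond",
    "calibrate_rf_units",
    "simulate_trial",
    "simulate_psychometric",
]


@dataclass(frozen=True)
class ReceptiveField:
    """Centre-surround field: +1 on the target, ``v_s`` <= 0 elsewhere.

    ``calibration_scale`` multiplies the whole field; it is 1 before
    calibration and is set by :func:`calibrate_rf_units` so that responses
    are measured in LRF units.
    """

    target_mask: np.ndarray
    surround_sensitivity: float = 0.0
    calibration_scale: float = 1.0

    def __post_init__(self) -> None:
        mask = np.asarray(self.target_mask, dtype=bool)
        object.__setattr__(self, "target_mask", mask)
        if self.surround_sensitivity > 0:
            raise ValueError("surround sensitivity must be <= 0")
        if self.calibration_scale <= 0:
            raise ValueError("calibration scale must be positive")
        if not mask.any() or mask.all():
            raise ValueError("target mask must be non-empty and smaller than the grid")

    def weights(self) -> np.ndarray:
        """Spatial weight grid (shared by the three cone classes)."""
        w = np.where(self.target_mask, 1.0, self.surround_sensitivity)
        return self.calibration_scale * w

    def vector(self) -> np.ndarray:
        """The field as a flat vector over (class, patch) — R in R^(3p)."""
        return np.tile(self.weights().ravel(), 3)


@dataclass(frozen=True)
class LINRFObserver:
    """Receptive field plus intrinsic Gaussian noise (sd in LRF units)."""

    rf: ReceptiveField
    intrinsic_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.intrinsic_sd < 0:
            raise ValueError("intrinsic noise sd must be non-negative")

    def to_json(self, path) -> None:
        payload = {
            "surround_sensitivity": self.rf.surround_sensitivity,
            "calibration_scale": self.rf.calibration_scale,
            "intrinsic_sd": self.intrinsic_sd,
            "shape": list(self.rf.target_mask.shape),
            "target_mask": self.rf.target_mask.astype(int).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "LINRFObserver":
        with open(path) as fh:
            payload = json.load(fh)
        rf = ReceptiveField(np.asarray(payload["target_mask"], dtype=bool),
                            payload["surround_sensitivity"],
                            payload["calibration_scale"])
        return cls(rf, payload["intrinsic_sd"])


def respond(obs: LINRFObserver, img: ConeImage,
            rng: np.random.Generator | None = None) -> float:
    """Visual response: R' I plus intrinsic Gaussian noise."""
    if img.shape != obs.rf.target_mask.shape:
        raise ValueError(
            f"image grid {img.shape} does not match receptive field "
            f"{obs.rf.target_mask.shape}")
    r = float((obs.rf.weights()[..., None] * img.responses).sum())
    if obs.intrinsic_sd > 0:
        rng = np.random.default_rng() if rng is None else rng
        r += rng.normal(0.0, obs.intrinsic_sd)
    return r


class ConditionSimulator:
    """Vectorized noise-free response sampler for one variation condition.

    Spatially uniform patches respond as units, so the class-summed,
    efficiency-normalized response of a patch is ``gain * integration_ms *
    (radiance . u)`` with ``u`` the summed cone weight.  A scene's
    noise-free field response is then

        cal * scale * (target_lrf * A + v_s * sum_j rho_j . v)

    with ``A = gain*T*(illuminant . u)`` and ``v = gain*T*(illuminant * u)``,
    which this class evaluates for thousands of scenes at once.  It matches
    the per-object path (render_scene -> to_cone_image -> respond) exactly
    for given draws.
    """

    def __init__(self, models: SceneModels, condition: Condition,
                 shape: tuple[int, int] = (5, 5),
                 target_mask: np.ndarray | None = None,
                 gain: float = 1.0,
                 integration_ms: float = DEFAULT_INTEGRATION_MS):
        self.models = models
        self.condition = condition
        self.mask = (default_target_mask(shape) if target_mask is None
                     else np.asarray(target_mask, dtype=bool))
        self.n_background = int((~self.mask).sum())
        u = summed_cone_weight()
        base = models.illuminant_base.values
        self._v = gain * integration_ms * base * u      # per-wavelength weight
        self._A = float((gain * integration_ms) * (base * u).sum())
        self._illum = models.illuminant_model(condition.delta)

    def noise_free_responses(self, target_lrf: float, n: int,
                             rng: np.random.Generator,
                             rf: ReceptiveField) -> np.ndarray:
        """Noise-free field responses for ``n`` independent scenes."""
        cond = self.condition
        scales = sample_illuminant_scales(self._illum, n, rng)
        bg = sample_reflectance_batch(self.models.reflectance, cond.sigma2,
                                      n * self.n_background, cond.mode, rng)
        bg_sum = (bg @ self._v).reshape(n, self.n_background).sum(axis=1)
        center = target_lrf * self._A * int(self.mask.sum())
        return rf.calibration_scale * scales * (
            center + rf.surround_sensitivity * bg_sum)

    def mean_response(self, target_lrf: float, n: int,
                      rng: np.random.Generator, rf: ReceptiveField) -> float:
        return float(self.noise_free_responses(target_lrf, n, rng, rf).mean())


def calibrate_rf_units(obs: LINRFObserver, simulator: ConditionSimulator,
                       lrf_levels=DEFAULT_LEVELS, n_scenes: int = 1000,
                       rng: np.random.Generator | None = None) -> LINRFObserver:
    """Rescale the receptive field so responses are in LRF units.

    Fits a least-squares slope of the mean noise-free response against the
    target LRF across ``lrf_levels`` (``n_scenes`` scenes per level when
    extrinsic variation is on) and divides the calibration scale by it, so
    the post-calibration slope is 1 and a response difference between two
    levels equals their LRF difference.
    """
    levels = np.asarray(lrf_levels, dtype=float)
    if np.unique(levels).size < 2:
        raise ValueError("need at least two distinct LRF levels to calibrate")
    rng = np.random.default_rng() if rng is None else rng
    cond = simulator.condition
    if cond.sigma2 == 0 and cond.delta == 0:
        n_scenes = 1  # scenes are deterministic without variation
    means = np.array([simulator.mean_response(x, n_scenes, rng, obs.rf)
                      for x in levels])
    slope = np.polyfit(levels, means, 1)[0]
    if slope <= 0:
        raise RuntimeError(
            "calibration failed: non-positive response slope "
            f"({slope:.3g}); surround too strong for this layout")
    rf = replace(obs.rf, calibration_scale=obs.rf.calibration_scale / slope)
    return replace(obs, rf=rf)


def simulate_trial(obs: LINRFObserver, standard_img: ConeImage,
                   comparison_img: ConeImage,
                   rng: np.random.Generator | None = None) -> str:
    """One 2AFC trial: choose the image with the larger visual response."""
    rng = np.random.default_rng() if rng is None else rng
    rs = respond(obs, standard_img, rng)
    rc = respond(obs, comparison_img, rng)
    if rc > rs:
        return "comparison"
    if rc < rs:
        return "standard"
    return "comparison" if rng.random() < 0.5 else "standard"


def simulate_psychometric(obs: LINRFObserver, simulator: ConditionSimulator,
                          levels=DEFAULT_LEVELS, n_per_level: int = 10_000,
                          rng: np.random.Generator | None = None,
                          standard_lrf: float = STANDARD_LRF) -> pd.DataFrame:
    """Simulate proportion-comparison-chosen data for one condition.

    For every comparison level, ``n_per_level`` independent trials are run
    with fresh scene draws for both intervals; returns a trial table with
    columns ``comparison_lrf``, ``n_trials``, ``n_comparison_chosen``.
    """
    rng = np.random.default_rng() if rng is None else rng
    levels = np.asarray(levels, dtype=float)
    if levels.min() < 0.35 - 1e-9 or levels.max() > 0.45 + 1e-9:
        raise ValueError("comparison levels must lie within [0.35, 0.45]")
    counts = np.empty(levels.size, dtype=int)
    for i, level in enumerate(levels):
        rs = simulator.noise_free_responses(standard_lrf, n_per_level, rng, obs.rf)
        rc = simulator.noise_free_responses(level, n_per_level, rng, obs.rf)
        if obs.intrinsic_sd > 0:
            rs = rs + rng.normal(0.0, obs.intrinsic_sd, n_per_level)
            rc = rc + rng.normal(0.0, obs.intrinsic_sd, n_per_level)
        chose_comparison = rc > rs
        ties = rc == rs
        if ties.any():
            chose_comparison = chose_comparison | (ties & (rng.random(n_per_level) < 0.5))
        counts[i] = int(chose_comparison.sum())
    return pd.DataFrame({
        "comparison_lrf": levels,
        "n_trials": np.full(levels.size, n_per_level, dtype=int),
        "n_comparison_chosen": counts,
    })
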