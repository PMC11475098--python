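"""Simplified image formation: patch-mosaic scenes and cone responses.

A stimulus is a small grid of spatially uniform patches (default 5 x 5)
with a central target patch.  Each background patch carries an independent
reflectance draw; the target carries a spectrally flat reflectance whose
value equals the requested luminous reflectance factor (flat spectra have
LRF equal to their reflectance by construction).  All patches share one
illuminant draw; patch radiance is the pointwise product of the illuminant
spectral power distribution and the patch reflectance.

The cone stage converts patch radiances to L, M, S responses: the expected
response is ``gain * integration_ms * sum_wl radiance * fundamental``, with
optional Poisson draws at that mean, and each class is then divided by its
integrated quantal efficiency so a spectrally flat stimulus produces equal
responses in the three classes.  A spatially uniform patch responds as a
unit, so this mosaic preserves the mathematics of a linear receptive field
applied to a rendered image at a fraction of the cost.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import colorimetry
from .reflectance import (IlluminantModel, ReflectancePCAModel,
                          sample_illuminant, sample_reflectance_batch)
from .spectral import DEFAULT_GRID, SpectralFunction

__all__ = [
    "Condition",
    "SceneModels",
    "StimulusImage",
    "ConeImage",
    "default_target_mask",
    "render_scene",
    "to_cone_image",
    "save_scene",
    "load_scene",
]

DEFAULT_SHAPE = (5, 5)
DEFAULT_INTEGRATION_MS = 100.0


@dataclass(frozen=True)
class Condition:
    """One variation condition: covariance scalar, range parameter, mode."""

    sigma2: float = 0.0
    delta: float = 0.0
    mode: str = "chromatic"

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.mode not in ("chromatic", "achromatic"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SceneModels:
    """The statistical generators a scene is drawn from."""

    reflectance: ReflectancePCAModel
    illuminant_base: SpectralFunction = field(
        default_factory=colorimetry.normalized_d65)

    def illuminant_model(self, delta: float) -> IlluminantModel:
        return IlluminantModel(self.illuminant_base, delta)


def default_target_mask(shape: tuple[int, int] = DEFAULT_SHAPE) -> np.ndarray:
    """Boolean mask marking the centre patch as the target region."""
    mask = np.zeros(shape, dtype=bool)
    mask[shape[0] // 2, shape[1] // 2] = True
    return mask


@dataclass(frozen=True)
class StimulusImage:
    """Patch-map of spectral radiances with a marked target region."""

    patch_radiances: np.ndarray  # (rows, cols, n_wl)
    target_mask: np.ndarray      # (rows, cols) bool
    target_lrf: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rad = np.asarray(self.patch_radiances, dtype=float)
        mask = np.asarray(self.target_mask, dtype=bool)
        object.__setattr__(self, "patch_radiances", rad)
        object.__setattr__(self, "target_mask", mask)
        if rad.ndim != 3 or mask.shape != rad.shape[:2]:
            raise ValueError("radiance grid and target mask shapes disagree")
        if not mask.any() or mask.all():
            raise ValueError("target mask must be non-empty and smaller than the grid")
        if rad.min() < -1e-12:
            raise ValueError("radiances must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.target_mask.shape


@dataclass(frozen=True)
class ConeImage:
    """Per-patch (L, M, S) responses; same grid as the source stimulus."""

    responses: np.ndarray  # (rows, cols, 3)
    noise_applied: bool = False

    def __post_init__(self) -> None:
        resp = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", resp)
        if resp.ndim != 3 or resp.shape[2] != 3:
            raise ValueError("cone responses must have shape (rows, cols, 3)")
        if resp.min() < 0:
            raise ValueError("cone responses must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.responses.shape[:2]


def render_scene(target_lrf: float, sigma2: float, delta: float,
                 mode: str, models: SceneModels,
                 rng: np.random.Generator | None = None,
                 shape: tuple[int, int] = DEFAULT_SHAPE,
                 target_mask: np.ndarray | None = None) -> StimulusImage:
    """Draw one scene: shared illuminant, independent background patches.

    The target patches carry the flat reflectance at ``target_lrf`` so the
    target's LRF is exact; each background patch gets an independent
    reflectance draw at the condition's covariance scalar.
    """
    if not 0.35 - 1e-9 <= target_lrf <= 0.45 + 1e-9:
        raise ValueError("target_lrf must lie in [0.35, 0.45]")
    rng = np.random.default_rng() if rng is None else rng
    mask = default_target_mask(shape) if target_mask is None else np.asarray(
        target_mask, dtype=bool)
    n_bg = int((~mask).sum())

    spd, scale = sample_illuminant(models.illuminant_model(delta), rng)
    bg = sample_reflectance_batch(models.reflectance, sigma2, n_bg, mode, rng)

    n_wl = spd.values.size
    refl = np.empty(mask.shape + (n_wl,))
    refl[mask] = target_lrf
    refl[~mask] = bg
    radiances = refl * spd.values  # broadcast over the last axis

    meta = {"sigma2": sigma2, "delta": delta, "mode": mode,
            "illuminant_scale": scale}
    return StimulusImage(radiances, mask, float(target_lrf), meta)


def cone_quantal_efficiencies() -> np.ndarray:
    """Integrated sensitivity of each cone class over the working grid."""
    return colorimetry.cone_sensitivities().sum(axis=0)


def summed_cone_weight() -> np.ndarray:
    """Spectral weight of the class-summed, efficiency-normalized response.

    For a noise-free patch, the sum over cone classes of the normalized
    responses equals ``gain * integration_ms * (radiance . u)`` with this
    vector ``u = sum_c fundamental_c / Q_c``.  Used by the fast batched
    simulation path.
    """
    fund = colorimetry.cone_sensitivities()
    return (fund / fund.sum(axis=0)).sum(axis=1)


def to_cone_image(img: StimulusImage, poisson: bool = False,
                  integration_ms: float = DEFAULT_INTEGRATION_MS,
                  gain: float = 1.0,
                  rng: np.random.Generator | None = None) -> ConeImage:
    """Convert patch radiances to normalized L, M, S cone responses."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    fund = colorimetry.cone_sensitivities()
    mean_counts = gain * integration_ms * (img.patch_radiances @ fund)
    if poisson:
        rng = np.random.default_rng() if rng is None else rng
        counts = rng.poisson(mean_counts).astype(float)
    else:
        counts = mean_counts
    normalized = counts / fund.sum(axis=0)
    return ConeImage(normalized, noise_applied=poisson)


# -- scene archive ------------------------------------------------------

def save_scene(img: StimulusImage, directory, name: str = "scene") -> None:
    """Write one scene as a spectral CSV plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows, cols, n_wl = img.patch_radiances.shape
    df = pd.DataFrame({"wavelength_nm": DEFAULT_GRID[:n_wl]})
    for r in range(rows):
        for c in range(cols):
            df[f"patch_{r}_{c}"] = img.patch_radiances[r, c]
    df.to_csv(directory / f"{name}.csv", index=False)
    sidecar = {
        "shape": [rows, cols],
        "target_mask": img.target_mask.astype(int).tolist(),
        "target_lrf": img.target_lrf,
        "meta": img.meta,
    }
    with open(directory / f"{name}.json", "w") as fh:
        json.dump(sidecar, fh)


def load_scene(directory, name: str = "scene") -> StimulusImage:
    """Reconstruct a scene written by :func:`save_scene`."""
    directory = Path(directory)
    df = pd.read_csv(directory / f"{name}.csv")
    with open(directory / f"{name}.json") as fh:
        sidecar = json.load(fh)
    rows, cols = sidecar["shape"]
    rad = np.empty((rows, cols, len(df)))
    for r in range(rows):
        for c in range(cols):
            rad[r, c] = df[f"patch_{r}_{c}"].to_numpy()
    mask = np.asarray(sidecar["target_mask"], dtype=bool)
    return StimulusImage(rad, mask, sidecar["target_lrf"], sidecar["meta"])
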