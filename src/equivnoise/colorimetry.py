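"""CIE colorimetry on the working grid.

Implements the colorimetric conventions used throughout: CIE 1931 2-degree
chromaticity, relative luminance, the luminous reflectance factor (LRF) of
a surface under the D65 reference illuminant, illuminant normalization, and
sRGB renditions for display.

The CIE 1931 2-degree colour-matching functions and the D65 spectral power
distribution are bundled as package data on the 400-700 nm / 10 nm grid
(the standard abridged 10 nm tabulations).  Integrals over wavelength are
rectangle-rule sums over the 31 grid samples.  Cone spectral sensitivities
are derived from the colour-matching functions by the Hunt-Pointer-Estevez
transformation (see :func:`cone_sensitivities`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .spectral import DEFAULT_GRID, InvalidSpectrumError, SpectralFunction

__all__ = [
    "Chromaticity",
    "cie_cmf",
    "d65",
    "normalized_d65",
    "cone_sensitivities",
    "normalize_illuminant",
    "compute_chromaticity",
    "compute_lrf",
    "srgb_rendition",
]


@dataclass(frozen=True)
class Chromaticity:
    """CIE 1931 xy chromaticity plus relative luminance Y."""

    x: float
    y: float
    Y: float

    def __post_init__(self) -> None:
        if not (0 < self.x < 1 and 0 < self.y < 1 and self.x + self.y < 1):
            raise ValueError(f"chromaticity ({self.x}, {self.y}) outside the xy triangle")
        if self.Y < 0:
            raise ValueError("relative luminance Y must be non-negative")


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("equivnoise.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=1)
def cie_cmf() -> np.ndarray:
    """CIE 1931 2-degree colour-matching functions, shape (31, 3)."""
    df = _load_table("cie_1931_2deg_cmf_10nm.csv")
    if not np.allclose(df["wavelength_nm"], DEFAULT_GRID):
        raise RuntimeError("bundled CMF table is not on the working grid")
    return df[["xbar", "ybar", "zbar"]].to_numpy(dtype=float)


@lru_cache(maxsize=1)
def d65() -> SpectralFunction:
    """CIE D65 illuminant on the working grid (standard relative values)."""
    df = _load_table("illuminant_d65_10nm.csv")
    return SpectralFunction(df["wavelength_nm"].to_numpy(dtype=float),
                            df["d65"].to_numpy(dtype=float), "power")


@lru_cache(maxsize=1)
def normalized_d65() -> SpectralFunction:
    """D65 divided by its mean power over wavelength (unit wavelength-mean)."""
    return normalize_illuminant(d65())


# Hunt-Pointer-Estevez XYZ -> LMS matrix (von Kries normalization: the
# equal-energy stimulus maps to L = M = S).
_HPE = np.array([
    [0.38971, 0.68898, -0.07868],
    [-0.22981, 1.18340, 0.04641],
    [0.00000, 0.00000, 1.00000],
])


@lru_cache(maxsize=1)
def cone_sensitivities() -> np.ndarray:
    """LMS cone spectral sensitivities, shape (31, 3).

    Obtained by applying the Hunt-Pointer-Estevez transformation to the
    CIE 1931 colour-matching functions; tiny negative lobes produced by the
    linear transform are clipped to zero so that cone responses to physical
    stimuli are non-negative.
    """
    lms = cie_cmf() @ _HPE.T
    return np.clip(lms, 0.0, None)


def _check_power(spd: SpectralFunction) -> None:
    if spd.kind != "power":
        raise InvalidSpectrumError("expected a power spectrum")
    if not np.any(spd.values > 0):
        raise InvalidSpectrumError("spectrum is identically zero")


def normalize_illuminant(spd: SpectralFunction) -> SpectralFunction:
    """Divide a power spectrum by its mean power over wavelength.

    The returned spectrum has unit wavelength-mean and the same relative
    shape (hence the same chromaticity) as the input.
    """
    _check_power(spd)
    return SpectralFunction(spd.wavelengths_nm, spd.values / spd.values.mean(), "power")


def tristimulus(spd: SpectralFunction) -> np.ndarray:
    """(X, Y, Z) by rectangle-rule summation against the bundled CMFs."""
    _check_power(spd)
    if len(spd) != len(DEFAULT_GRID) or not np.allclose(spd.wavelengths_nm, DEFAULT_GRID):
        raise InvalidSpectrumError("colorimetry requires the 400-700/10 nm working grid")
    return spd.values @ cie_cmf()


def compute_chromaticity(spd: SpectralFunction) -> Chromaticity:
    """CIE 1931 2-degree chromaticity (x, y) and relative luminance Y."""
    X, Y, Z = tristimulus(spd)
    s = X + Y + Z
    return Chromaticity(x=X / s, y=Y / s, Y=Y)


def luminance(spd: SpectralFunction) -> float:
    """Relative luminance: the Y tristimulus value (arbitrary units)."""
    return float(tristimulus(spd)[1])


def compute_lrf(reflectance: SpectralFunction,
                reference: SpectralFunction | None = None) -> float:
    """Luminous reflectance factor of a surface under the reference illuminant.

    The LRF is the luminance of the surface rendered under the reference
    illuminant (D65 by default) divided by the luminance of the illuminant
    itself.  For a spectrally flat surface it equals the reflectance value.
    """
    if reflectance.kind != "reflectance":
        raise InvalidSpectrumError("compute_lrf expects a reflectance spectrum")
    ref = normalized_d65() if reference is None else reference
    if not reflectance.same_grid(ref):
        raise InvalidSpectrumError("reflectance and reference grids differ")
    if not np.any(reflectance.values > 0):
        return 0.0
    rendered = SpectralFunction(ref.wavelengths_nm,
                                ref.values * reflectance.values, "power")
    return luminance(rendered) / luminance(ref)


# sRGB (IEC 61966-2-1) linear transform from CIE XYZ, D65 white point.
_XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


def _gamma_encode(linear: np.ndarray) -> np.ndarray:
    a = 0.055
    return np.where(linear <= 0.0031308,
                    12.92 * linear,
                    (1 + a) * np.power(np.clip(linear, 0, None), 1 / 2.4) - a)


def srgb_rendition(spd: SpectralFunction, scale: float = 1.0) -> tuple[float, float, float]:
    """Gamma-encoded sRGB triple for a power spectrum.

    ``scale`` multiplies the XYZ values before conversion and should be
    chosen so the rendition stays in gamut; out-of-gamut values are clipped
    to [0, 1] with a warning.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if not np.any(spd.values > 0):
        return (0.0, 0.0, 0.0)
    xyz = tristimulus(spd) * scale
    # Normalize so Y of the grid-adapted D65 white maps to 1.
    xyz = xyz / luminance(normalized_d65())
    rgb_lin = _XYZ_TO_SRGB @ xyz
    if rgb_lin.min() < -1e-9 or rgb_lin.max() > 1 + 1e-9:
        warnings.warn("sRGB rendition out of gamut; clipping to [0, 1]",
                      stacklevel=2)
    rgb = _gamma_encode(np.clip(rgb_lin, 0.0, 1.0))
    return tuple(float(v) for v in np.clip(rgb, 0.0, 1.0))
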