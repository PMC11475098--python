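"""Spectral functions on the working wavelength grid.

Everything downstream (reflectance statistics, scene rendering, cone
responses, colorimetry) operates on a fixed 31-sample grid, 400-700 nm in
10 nm steps.  A :class:`SpectralFunction` is a real-valued function of
wavelength on that grid, either a surface reflectance (values in [0, 1])
or a radiant power distribution (values >= 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_GRID",
    "SpectralFunction",
    "read_spectra_csv",
    "write_spectra_csv",
]

#: Working wavelength grid: 400-700 nm, 10 nm step, 31 samples.
DEFAULT_GRID = np.arange(400.0, 701.0, 10.0)

Kind = Literal["reflectance", "power"]


class InvalidSpectrumError(ValueError):
    """Raised when spectral values violate the invariants of their kind."""


@dataclass(frozen=True)
class SpectralFunction:
    """A sampled spectrum: reflectance in [0, 1] or radiant power >= 0.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelength grid in nanometres.
    values
        Spectral values, one per wavelength.
    kind
        ``"reflectance"`` (values in [0, 1]) or ``"power"`` (values >= 0).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: Kind = "reflectance"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise InvalidSpectrumError(
                f"wavelengths {wl.shape} and values {vals.shape} must be "
                "1-d arrays of equal length"
            )
        if wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise InvalidSpectrumError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(vals)):
            raise InvalidSpectrumError("spectral values must be finite")
        if self.kind == "reflectance":
            if vals.min() < -1e-12 or vals.max() > 1 + 1e-12:
                raise InvalidSpectrumError(
                    f"reflectance values must lie in [0, 1]; got range "
                    f"[{vals.min():.4g}, {vals.max():.4g}]"
                )
        elif self.kind == "power":
            if vals.min() < -1e-12:
                raise InvalidSpectrumError("power values must be non-negative")
        else:
            raise InvalidSpectrumError(f"unknown kind {self.kind!r}")

    @classmethod
    def flat(cls, value: float, kind: Kind = "reflectance",
             wavelengths_nm: np.ndarray | None = None) -> "SpectralFunction":
        """A spectrally flat function of the given constant value."""
        wl = DEFAULT_GRID if wavelengths_nm is None else np.asarray(wavelengths_nm)
        return cls(wl, np.full(wl.shape, float(value)), kind)

    def scaled(self, factor: float) -> "SpectralFunction":
        """Multiply a power spectrum by a positive scalar."""
        if self.kind != "power":
            raise InvalidSpectrumError("scaling is defined for power spectra")
        return SpectralFunction(self.wavelengths_nm, self.values * factor, "power")

    def same_grid(self, other: "SpectralFunction") -> bool:
        return (
            self.wavelengths_nm.shape == other.wavelengths_nm.shape
            and np.allclose(self.wavelengths_nm, other.wavelengths_nm)
        )

    def __len__(self) -> int:
        return self.wavelengths_nm.size


def _as_matrix(spectra: Iterable[SpectralFunction]) -> tuple[np.ndarray, np.ndarray]:
    """Stack spectra sharing a common grid into an (n, n_wl) matrix."""
    spectra = list(spectra)
    if not spectra:
        raise InvalidSpectrumError("empty spectrum collection")
    wl = spectra[0].wavelengths_nm
    for s in spectra[1:]:
        if not spectra[0].same_grid(s):
            raise InvalidSpectrumError("spectra are not on a common wavelength grid")
    return wl, np.vstack([s.values for s in spectra])


def read_spectra_csv(path, kind: Kind = "reflectance") -> list[SpectralFunction]:
    """Read spectra from the package CSV dialect.

    The file has a header ``wavelength_nm,<name1>,<name2>,...`` and one row
    per wavelength; each non-wavelength column is one spectrum.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise InvalidSpectrumError(
            f"first column of {path} must be 'wavelength_nm', got {df.columns[0]!r}"
        )
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    return [
        SpectralFunction(wl, df[c].to_numpy(dtype=float), kind)
        for c in df.columns[1:]
    ]


def write_spectra_csv(path, spectra: Iterable[SpectralFunction],
                      names: Iterable[str] | None = None) -> None:
    """Write spectra to the package CSV dialect (columns share one grid)."""
    wl, mat = _as_matrix(spectra)
    names = list(names) if names is not None else [f"s{i}" for i in range(len(mat))]
    if len(names) != len(mat):
        raise ValueError("one name per spectrum required")
    df = pd.DataFrame({"wavelength_nm": wl})
    for name, row in zip(names, mat):
        df[name] = row
    df.to_csv(path, index=False)
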