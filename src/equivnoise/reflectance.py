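"""Statistical models of scene spectral variation.

Two generators drive every variation condition in the pipeline:

* a PCA / multivariate-normal model of natural surface reflectance.  A
  reflectance ensemble is mean-centred and projected onto the eigenvectors
  of its sample covariance with the six largest eigenvalues; new spectra
  are drawn by sampling projection weights from a mean-zero multivariate
  normal whose covariance is the sample weight covariance multiplied by a
  *covariance scalar* sigma^2 (0 = no variation, 1 = natural-dataset
  variability).  Draws violating physical realizability (any value outside
  [0, 1]) are discarded and redrawn.  In achromatic mode an accepted
  spectrum is replaced by the flat spectrum at its wavelength-mean.

* a light-source intensity model: a fixed relative shape (normalized D65)
  multiplied by a scalar drawn from the log-uniform distribution on
  [1 - delta, 1 + delta], where the *range parameter* delta controls the
  spread.  All light sources in a scene share one draw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from . import colorimetry
from .spectral import DEFAULT_GRID, InvalidSpectrumError, SpectralFunction, _as_matrix

__all__ = [
    "ReflectancePCAModel",
    "IlluminantModel",
    "SamplingError",
    "fit_reflectance_pca",
    "sample_reflectance",
    "sample_reflectance_batch",
    "sample_illuminant",
    "CHROMATIC_SIGMA2_GRID",
    "ACHROMATIC_SIGMA2_GRID",
    "DELTA_GRID",
]

#: Default condition grids for the three variation experiments.
CHROMATIC_SIGMA2_GRID = (0.0, 0.01, 0.03, 0.1, 0.3, 1.0)
ACHROMATIC_SIGMA2_GRID = (0.03, 0.3, 1.0)
DELTA_GRID = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30)

#: Per-sample redraw budget for the realizability rejection loop.
REJECTION_BUDGET = 10_000


class SamplingError(RuntimeError):
    """Raised when the realizability rejection budget is exhausted."""


@dataclass(frozen=True)
class ReflectancePCAModel:
    """Low-rank multivariate-normal model of surface reflectance.

    Attributes
    ----------
    mean_spectrum
        Ensemble mean reflectance.
    basis
        (k, n_wl) orthonormal eigenvector rows spanning the retained
        principal subspace.
    weight_covariance
        (k, k) sample covariance of the projection weights; symmetric PSD.
    """

    mean_spectrum: SpectralFunction
    basis: np.ndarray
    weight_covariance: np.ndarray

    def __post_init__(self) -> None:
        basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        cov = np.atleast_2d(np.asarray(self.weight_covariance, dtype=float))
        object.__setattr__(self, "basis", basis)
        object.__setattr__(self, "weight_covariance", cov)
        k, n = basis.shape
        if n != len(self.mean_spectrum):
            raise InvalidSpectrumError("basis length does not match the grid")
        if not np.allclose(basis @ basis.T, np.eye(k), atol=1e-8):
            raise ValueError("basis vectors must be mutually orthonormal")
        if cov.shape != (k, k) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("weight covariance must be k x k symmetric")
        if np.linalg.eigvalsh(cov).min() < -1e-10 * max(1.0, np.abs(cov).max()):
            raise ValueError("weight covariance must be positive semidefinite")

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    def covariance_factor(self) -> np.ndarray:
        """A matrix A with A @ A.T == weight_covariance (eigen square root)."""
        evals, evecs = np.linalg.eigh(self.weight_covariance)
        return evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    # -- serialization -------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "wavelengths_nm": self.mean_spectrum.wavelengths_nm.tolist(),
            "mean_spectrum": self.mean_spectrum.values.tolist(),
            "basis": self.basis.tolist(),
            "weight_covariance": self.weight_covariance.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReflectancePCAModel":
        with open(path) as fh:
            payload = json.load(fh)
        mean = SpectralFunction(np.asarray(payload["wavelengths_nm"]),
                                np.asarray(payload["mean_spectrum"]), "reflectance")
        return cls(mean, np.asarray(payload["basis"]),
                   np.asarray(payload["weight_covariance"]))


@dataclass(frozen=True)
class IlluminantModel:
    """Fixed-shape illuminant with log-uniform intensity scatter.

    ``base_spd`` must have unit wavelength-mean; ``delta`` in [0, 1) is the
    half-width of the multiplicative interval [1 - delta, 1 + delta].
    """

    base_spd: SpectralFunction = field(default_factory=colorimetry.normalized_d65)
    delta: float = 0.0

    def __post_init__(self) -> None:
        if not np.isclose(self.base_spd.values.mean(), 1.0):
            raise InvalidSpectrumError("base_spd must have unit wavelength-mean")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError(
                f"delta must lie in [0, 1); got {self.delta} "
                "(delta >= 1 would include zero intensity)"
            )


def fit_reflectance_pca(dataset, n_components: int = 6
                        ) -> tuple[ReflectancePCAModel, float]:
    """Fit the PCA reflectance model to an ensemble of spectra.

    Returns the model together with the fraction of total variance captured
    by the retained components.  A zero-variance ensemble is degenerate;
    its explained fraction is defined as 1.0.
    """
    wl, mat = _as_matrix(dataset)
    n, n_wl = mat.shape
    if n < n_components + 1:
        raise ValueError(
            f"need at least {n_components + 1} spectra to fit "
            f"{n_components} components; got {n}"
        )
    mean = mat.mean(axis=0)
    centered = mat - mean
    total_var = centered.var(axis=0, ddof=1).sum()
    if total_var <= 0:
        # All spectra identical: keep an arbitrary orthonormal basis and a
        # zero weight covariance.
        basis = np.eye(n_wl)[:n_components]
        model = ReflectancePCAModel(
            SpectralFunction(wl, mean, "reflectance"), basis,
            np.zeros((n_components, n_components)))
        return model, 1.0
    pca = PCA(n_components=n_components, svd_solver="full")
    weights = pca.fit_transform(centered)
    model = ReflectancePCAModel(
        SpectralFunction(wl, mean, "reflectance"),
        pca.components_,
        np.cov(weights, rowvar=False),
    )
    return model, float(pca.explained_variance_ratio_.sum())


def sample_reflectance_batch(model: ReflectancePCAModel, sigma2: float, n: int,
                             mode: str = "chromatic",
                             rng: np.random.Generator | None = None,
                             max_redraws: int = REJECTION_BUDGET) -> np.ndarray:
    """Draw ``n`` realizable reflectance spectra, returned as an (n, 31) array.

    Vectorized rejection sampler used by both the public single-spectrum
    API and the scene renderer: weights ~ N(0, sigma2 * weight_covariance),
    spectrum = mean + basis' weights, redrawn until every value lies in
    [0, 1].  ``mode='achromatic'`` replaces each accepted spectrum by the
    flat spectrum at its wavelength-mean.
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if mode not in ("chromatic", "achromatic"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng() if rng is None else rng
    mean = model.mean_spectrum.values
    if sigma2 == 0:
        out = np.tile(mean, (n, 1))
    else:
        factor = np.sqrt(sigma2) * model.covariance_factor()
        out = np.empty((n, mean.size))
        remaining = np.arange(n)
        for _ in range(max_redraws):
            z = rng.standard_normal((remaining.size, model.n_components))
            cand = mean + (z @ factor.T) @ model.basis
            ok = (cand >= 0.0).all(axis=1) & (cand <= 1.0).all(axis=1)
            out[remaining[ok]] = cand[ok]
            remaining = remaining[~ok]
            if remaining.size == 0:
                break
        else:
            raise SamplingError(
                f"realizability rejection budget ({max_redraws}) exhausted "
                f"at sigma2={sigma2}"
            )
    if mode == "achromatic":
        out = np.tile(out.mean(axis=1, keepdims=True), (1, mean.size))
    return out


def sample_reflectance(model: ReflectancePCAModel, sigma2: float,
                       mode: str = "chromatic",
                       rng: np.random.Generator | None = None) -> SpectralFunction:
    """Draw one physically realizable reflectance spectrum from the model."""
    vals = sample_reflectance_batch(model, sigma2, 1, mode, rng)[0]
    return SpectralFunction(model.mean_spectrum.wavelengths_nm, vals, "reflectance")


def sample_illuminant(model: IlluminantModel,
                      rng: np.random.Generator | None = None
                      ) -> tuple[SpectralFunction, float]:
    """Draw one illuminant: base shape times a log-uniform intensity scale.

    The scale is exp(U) with U uniform on [ln(1 - delta), ln(1 + delta)];
    at delta = 0 the scale is exactly 1.  Returns (spd, scale).
    """
    rng = np.random.default_rng() if rng is None else rng
    if model.delta == 0.0:
        return model.base_spd, 1.0
    lo, hi = np.log1p(-model.delta), np.log1p(model.delta)
    scale = float(np.exp(rng.uniform(lo, hi)))
    return model.base_spd.scaled(scale), scale


def sample_illuminant_scales(model: IlluminantModel, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Vectorized intensity-scale draws (one per scene)."""
    if model.delta == 0.0:
        return np.ones(n)
    lo, hi = np.log1p(-model.delta), np.log1p(model.delta)
    return np.exp(rng.uniform(lo, hi, size=n))
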