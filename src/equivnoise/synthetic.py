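"""Synthetic inputs with the statistical structure the analysis assumes.

Two generators make the whole pipeline testable without any external data:

* a surrogate natural-reflectance ensemble — smooth, physically realizable
  spectra with low-rank covariance, standing in for measured surface
  reflectance databases.  Spectra are drawn from a Gaussian process with a
  squared-exponential wavelength correlation, so almost all variance falls
  in a handful of principal components, as in measured ensembles.  The
  surrogate matches only these structural assumptions (smoothness, low
  rank, realizability), not the chromaticity gamut of natural surfaces.

* simulated two-alternative forced-choice (2AFC) trial tables from a known
  lapse-adjusted cumulative-normal psychometric function, emulating
  per-block proportion-comparison-chosen data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .spectral import DEFAULT_GRID, SpectralFunction

__all__ = [
    "SurrogateDatasetSpec",
    "GroundTruthPsychometric",
    "make_surrogate_dataset",
    "generate_trial_table",
    "DEFAULT_LEVELS",
    "STANDARD_LRF",
]

#: Standard target LRF and the 11 equally spaced comparison levels.
STANDARD_LRF = 0.40
DEFAULT_LEVELS = tuple(float(x) for x in np.round(np.linspace(0.35, 0.45, 11), 4))


@dataclass(frozen=True)
class SurrogateDatasetSpec:
    """Parameters of the surrogate reflectance ensemble.

    ``smoothness_scale_nm`` is the correlation length of spectral wiggles;
    ``amplitude`` the pointwise standard deviation around ``mean_level``.
    The defaults produce 632 spectra (the size of the combined natural
    ensembles the reflectance model is calibrated against) whose top six
    principal components carry essentially all variance.
    """

    n_spectra: int = 632
    smoothness_scale_nm: float = 80.0
    mean_level: float = 0.45
    amplitude: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spectra < 10:
            raise ValueError("n_spectra must be at least 10")
        if not 0 < self.mean_level < 1:
            raise ValueError("mean_level must lie in (0, 1)")
        if self.amplitude <= 0 or self.smoothness_scale_nm <= 0:
            raise ValueError("amplitude and smoothness scale must be positive")


def make_surrogate_dataset(spec: SurrogateDatasetSpec) -> list[SpectralFunction]:
    """Generate the surrogate ensemble of smooth reflectances in [0, 1].

    Raw Gaussian-process draws that leave [0, 1] are rejected and redrawn;
    if more than 1% of raw draws fail realizability the parameter
    combination is considered invalid and a ``ValueError`` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    wl = DEFAULT_GRID
    d2 = (wl[:, None] - wl[None, :]) ** 2
    cov = spec.amplitude ** 2 * np.exp(-d2 / (2 * spec.smoothness_scale_nm ** 2))
    evals, evecs = np.linalg.eigh(cov)
    factor = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))

    spectra = np.empty((spec.n_spectra, wl.size))
    filled = 0
    attempted = 0
    while filled < spec.n_spectra:
        want = spec.n_spectra - filled
        z = rng.standard_normal((want, wl.size))
        cand = spec.mean_level + z @ factor.T
        attempted += want
        ok = (cand >= 0.0).all(axis=1) & (cand <= 1.0).all(axis=1)
        good = cand[ok]
        spectra[filled:filled + good.shape[0]] = good
        filled += good.shape[0]
        if attempted >= 10 * spec.n_spectra:
            break
    if filled < spec.n_spectra or filled / attempted < 0.99:
        raise ValueError(
            "amplitude/smoothness combination fails realizability for more "
            f"than 1% of draws (acceptance {filled / attempted:.3f}); "
            "reduce amplitude or increase mean_level margin"
        )
    return [SpectralFunction(wl, row, "reflectance") for row in spectra]


@dataclass(frozen=True)
class GroundTruthPsychometric:
    """Known psychometric ground truth for simulated responses.

    The response model is the lapse-adjusted cumulative normal
    ``psi(x) = lapse + (1 - 2*lapse) * Phi((x - pse) / slope_sd)`` with the
    guess rate constrained equal to the lapse rate.
    """

    pse: float = STANDARD_LRF
    slope_sd: float = 0.02
    lapse: float = 0.0
    levels: tuple = DEFAULT_LEVELS
    n_per_level: int = 30

    def __post_init__(self) -> None:
        if self.slope_sd <= 0:
            raise ValueError("slope_sd must be positive")
        if not 0.0 <= self.lapse <= 0.05:
            raise ValueError("lapse must lie in [0, 0.05]")
        if self.n_per_level < 1:
            raise ValueError("n_per_level must be positive")
        levels = np.asarray(self.levels, dtype=float)
        if levels.min() < 0.35 - 1e-9 or levels.max() > 0.45 + 1e-9:
            raise ValueError("levels must lie within [0.35, 0.45]")

    def psi(self, x) -> np.ndarray:
        """Probability of choosing the comparison at comparison LRF ``x``."""
        x = np.asarray(x, dtype=float)
        return self.lapse + (1 - 2 * self.lapse) * norm.cdf(
            (x - self.pse) / self.slope_sd)


def generate_trial_table(truth: GroundTruthPsychometric,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Simulate binomial 2AFC counts at each comparison level.

    Returns a trial table with columns ``comparison_lrf``, ``n_trials`` and
    ``n_comparison_chosen``; total trials are
    ``n_per_level * len(levels)`` (330 for the default 30 x 11 block).
    """
    rng = np.random.default_rng() if rng is None else rng
    levels = np.asarray(truth.levels, dtype=float)
    p = truth.psi(levels)
    chosen = rng.binomial(truth.n_per_level, p)
    return pd.DataFrame({
        "comparison_lrf": levels,
        "n_trials": np.full(levels.size, truth.n_per_level, dtype=int),
        "n_comparison_chosen": chosen.astype(int),
    })
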