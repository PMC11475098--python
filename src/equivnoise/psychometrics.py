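"""Maximum-likelihood cumulative-normal psychometric fitting.

The psychometric function is the lapse-adjusted cumulative normal

    psi(x) = lambda + (1 - 2*lambda) * Phi((x - pse) / sd)

with the guess rate constrained equal to the lapse rate ``lambda`` and
``lambda`` restricted to [0, 0.05].  Parameters are estimated by
maximizing the binomial log-likelihood of the per-level comparison-chosen
counts; the optimization uses a fixed deterministic multi-start grid with
bounded local refinement, so fits are reproducible without a seed.

The discrimination threshold ``T`` is the difference between the stimulus
levels at which the *fitted* function equals 0.76 and 0.50 — the level
difference that corresponds to a d-prime of 1 in a two-interval task.
Inverting the full lapse-adjusted psi gives

    T = sd * Phi^-1((0.76 - lambda) / (1 - 2*lambda))

(the 0.50 point is the PSE for any lambda).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "PsychometricModel",
    "PsychometricResults",
    "DegenerateDataError",
    "fit_psychometric",
    "threshold_from_fit",
    "screen_observer",
]

MAX_LAPSE = 0.05
_CRITERION = 0.76


class DegenerateDataError(ValueError):
    """Raised when responses carry no information about the slope."""


def _clean_table(trials: pd.DataFrame) -> pd.DataFrame:
    required = {"comparison_lrf", "n_trials", "n_comparison_chosen"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table is missing columns {sorted(missing)}")
    merged = (trials.groupby("comparison_lrf", as_index=False)
              [["n_trials", "n_comparison_chosen"]].sum()
              .sort_values("comparison_lrf"))
    if (merged["n_comparison_chosen"] > merged["n_trials"]).any():
        raise ValueError("n_comparison_chosen exceeds n_trials")
    if len(merged) < 3:
        raise ValueError("need trials at three or more distinct levels")
    return merged


class PsychometricModel:
    """Binomial cumulative-normal model of a 2AFC trial table.

    Parameters
    ----------
    trials
        Trial table with columns ``comparison_lrf``, ``n_trials``,
        ``n_comparison_chosen``.  Rows with duplicate levels are merged.
    """

    def __init__(self, trials: pd.DataFrame):
        table = _clean_table(trials)
        self.levels = table["comparison_lrf"].to_numpy(dtype=float)
        self.n = table["n_trials"].to_numpy(dtype=float)
        self.k = table["n_comparison_chosen"].to_numpy(dtype=float)
        if self.k.sum() == 0 or (self.n - self.k).sum() == 0:
            raise DegenerateDataError(
                "all responses identical: the slope is unidentifiable; "
                "collect trials spanning the transition region")

    @classmethod
    def from_dataframe(cls, trials: pd.DataFrame) -> "PsychometricModel":
        return cls(trials)

    @staticmethod
    def psi(x, pse: float, sd: float, lapse: float) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return lapse + (1 - 2 * lapse) * norm.cdf((x - pse) / sd)

    def loglike(self, pse: float, sd: float, lapse: float) -> float:
        p = np.clip(self.psi(self.levels, pse, sd, lapse), 1e-12, 1 - 1e-12)
        return float((self.k * np.log(p) + (self.n - self.k) * np.log1p(-p)).sum())

    def _neg_loglike(self, theta: np.ndarray) -> float:
        pse, log_sd, lapse = theta
        return -self.loglike(pse, np.exp(log_sd), lapse)

    def fit(self) -> "PsychometricResults":
        """Maximize the binomial likelihood over (pse, sd, lapse)."""
        span = self.levels.max() - self.levels.min()
        pse_starts = np.quantile(self.levels, [0.25, 0.5, 0.75])
        sd_starts = span * np.array([0.05, 0.15, 0.5])
        bounds = [
            (self.levels.min() - span, self.levels.max() + span),
            (np.log(span * 1e-3), np.log(span * 20)),
            (0.0, MAX_LAPSE),
        ]
        best = None
        for pse0 in pse_starts:
            for sd0 in sd_starts:
                res = minimize(self._neg_loglike,
                               x0=np.array([pse0, np.log(sd0), 0.01]),
                               method="L-BFGS-B", bounds=bounds)
                if best is None or res.fun < best.fun:
                    best = res
        pse, log_sd, lapse = best.x
        return PsychometricResults(self, float(pse), float(np.exp(log_sd)),
                                   float(lapse), float(-best.fun))


@dataclass(frozen=True)
class PsychometricResults:
    """Fitted psychometric parameters and derived threshold."""

    model: PsychometricModel
    pse: float
    sd: float
    lapse: float
    log_likelihood: float

    @property
    def threshold(self) -> float:
        """T = psi^-1(0.76) - psi^-1(0.50) of the fitted lapse-adjusted curve."""
        return threshold_from_fit(self)

    def predict(self, x) -> np.ndarray:
        return PsychometricModel.psi(x, self.pse, self.sd, self.lapse)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "parameter": ["pse", "sd", "lapse", "threshold", "log_likelihood"],
            "value": [self.pse, self.sd, self.lapse, self.threshold,
                      self.log_likelihood],
        })

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"PsychometricResults(pse={self.pse:.4f}, sd={self.sd:.4f}, "
                f"lapse={self.lapse:.3f}, threshold={self.threshold:.4f})")


def fit_psychometric(trials: pd.DataFrame) -> PsychometricResults:
    """Fit the lapse-adjusted cumulative normal to a trial table."""
    return PsychometricModel(trials).fit()


def threshold_from_fit(fit, criterion: float = _CRITERION,
                       use_lapse_adjusted: bool = True) -> float:
    """Threshold under the 0.76/0.50 convention.

    Inverts the fitted psychometric function at ``criterion`` and 0.50 and
    returns the level difference.  With ``use_lapse_adjusted=False`` the
    underlying lapse-free cumulative normal is inverted instead.
    """
    if use_lapse_adjusted:
        p = (criterion - fit.lapse) / (1 - 2 * fit.lapse)
        if not 0 < p < 1:
            raise ValueError("criterion unattainable at this lapse rate")
    else:
        p = criterion
    return float(fit.sd * norm.ppf(p))


def screen_observer(practice_thresholds) -> bool:
    """Practice-session screen: pass iff the mean threshold of the last two
    of three practice blocks is not larger than 0.030."""
    t = np.asarray(practice_thresholds, dtype=float)
    if t.shape != (3,):
        raise ValueError("exactly three practice-block thresholds required")
    return bool(t[-2:].mean() <= 0.030)
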