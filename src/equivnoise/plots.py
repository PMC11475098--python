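"""Diagnostic figures for threshold curves and variance decompositions."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

__all__ = ["plot_noise_curve", "plot_decomposition", "plot_psychometric"]


def plot_noise_curve(levels, mean_t2, fit=None, ax=None, label="measured"):
    """log T^2 against condition level, with the fitted curve if given."""
    if ax is None:
        _, ax = plt.subplots()
    levels = np.asarray(levels, dtype=float)
    ax.plot(levels, np.log10(mean_t2), "o", label=label)
    if fit is not None:
        grid = np.linspace(levels.min(), levels.max(), 200)
        ax.plot(grid, np.log10(fit.sigma_i2 + grid * fit.sigma_e02), "-",
                label=f"fit: si2={fit.sigma_i2:.2e}, se02={fit.sigma_e02:.2e}")
    ax.set_xlabel("condition level (sigma^2 or delta)")
    ax.set_ylabel("log10 T^2")
    ax.legend()
    return ax


def plot_decomposition(decomp, ax=None):
    """Bar chart of the extrinsic-variance increases and their sum."""
    if ax is None:
        _, ax = plt.subplots()
    individual = [k for k in decomp.delta_t2
                  if k not in ("none", "simultaneous")]
    names = individual + ["sum of individual", "simultaneous"]
    values = [decomp.delta_t2[k] for k in individual]
    values += [decomp.sum_individual, decomp.delta_t2["simultaneous"]]
    ax.bar(names, values)
    ax.set_ylabel("increase in squared threshold")
    ax.tick_params(axis="x", rotation=20)
    return ax


def plot_psychometric(fit, ax=None):
    """Observed proportions and the fitted cumulative normal."""
    if ax is None:
        _, ax = plt.subplots()
    m = fit.model
    ax.plot(m.levels, m.k / m.n, "o", label="observed")
    grid = np.linspace(m.levels.min(), m.levels.max(), 200)
    ax.plot(grid, fit.predict(grid), "-",
            label=f"fit: T={fit.threshold:.4f}")
    ax.set_xlabel("comparison LRF")
    ax.set_ylabel("proportion comparison chosen")
    ax.legend()
    return ax
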