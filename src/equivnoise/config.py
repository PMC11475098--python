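"""Experiment configuration and deterministic seed derivation.

One global seed expands into independent per-stage random streams through
``numpy.random.SeedSequence(seed, spawn_key=(STAGES[name],))``, so any
stage can be re-run in isolation and two runs of the same config are
bit-identical.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .reflectance import CHROMATIC_SIGMA2_GRID, DELTA_GRID
from .synthetic import DEFAULT_LEVELS, STANDARD_LRF

__all__ = ["ExperimentConfig", "stage_rng", "STAGES"]

#: Fixed stage order for seed derivation.
STAGES = {
    "surrogate": 0,
    "spectra": 1,
    "render": 2,
    "simulate": 3,
    "psychometrics": 4,
    "noise_fit": 5,
    "decompose": 6,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child random stream for one named pipeline stage."""
    if stage not in STAGES:
        raise KeyError(f"unknown stage {stage!r}; known: {sorted(STAGES)}")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(STAGES[stage],)))


@dataclass
class ExperimentConfig:
    """Full configuration of a synthetic replication run."""

    seed: int = 0
    sigma2_grid: tuple = CHROMATIC_SIGMA2_GRID
    delta_grid: tuple = DELTA_GRID
    mode: str = "chromatic"
    levels: tuple = DEFAULT_LEVELS
    standard_lrf: float = STANDARD_LRF
    n_per_level: int = 30
    grid_shape: tuple = (5, 5)
    surround_sensitivity: float = -0.1
    intrinsic_sd: float = 0.02
    n_surrogate: int = 632

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        # YAML round-trips tuples as lists; normalize.
        cfg.sigma2_grid = tuple(cfg.sigma2_grid)
        cfg.delta_grid = tuple(cfg.delta_grid)
        cfg.levels = tuple(cfg.levels)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    def rng(self, stage: str) -> np.random.Generator:
        return stage_rng(self.seed, stage)
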