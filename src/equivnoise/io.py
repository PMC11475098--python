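"""Readers and writers for the pipeline's CSV/JSON artifacts.

Schemas
-------
Trial table CSV
    ``condition, block, comparison_lrf, n_trials, n_comparison_chosen`` —
    one row per comparison level; the same schema external per-observer
    proportion-comparison-chosen tables can be mapped onto.
Threshold summary CSV
    ``observer, condition, block, pse, sd, lapse, threshold`` — one row
    per fitted block.
"""

from __future__ import annotations

import json

import pandas as pd

TRIAL_COLUMNS = ["condition", "block", "comparison_lrf", "n_trials",
                 "n_comparison_chosen"]
SUMMARY_COLUMNS = ["observer", "condition", "block", "pse", "sd", "lapse",
                   "threshold"]

__all__ = [
    "TRIAL_COLUMNS",
    "SUMMARY_COLUMNS",
    "write_trial_table",
    "read_trial_table",
    "write_threshold_summary",
    "read_threshold_summary",
    "write_fit_json",
    "read_fit_json",
]


def write_trial_table(path, table: pd.DataFrame, condition: str = "default",
                      block: int = 1) -> None:
    """Write a trial table, adding condition/block labels if absent."""
    out = table.copy()
    if "condition" not in out.columns:
        out.insert(0, "condition", condition)
    if "block" not in out.columns:
        out.insert(1, "block", block)
    out[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trial_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table {path} is missing columns {sorted(missing)}")
    return df[TRIAL_COLUMNS]


def write_threshold_summary(path, rows: pd.DataFrame) -> None:
    missing = set(SUMMARY_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"summary is missing columns {sorted(missing)}")
    rows[SUMMARY_COLUMNS].to_csv(path, index=False)


def read_threshold_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary {path} is missing columns {sorted(missing)}")
    return df[SUMMARY_COLUMNS]


def write_fit_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_fit_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
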