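"""Behavioral-style trial tables: one chosen outcome per generalization trial.

The CSV schema mirrors the public dataset of the original magic-stones
experiments: one row per (participant, trial) with the trial's agent and
recipient features, the chosen result features, and condition/order
metadata.  Experiment 1 columns use color/shape strings, Experiment 2
analogues use shade/edge integers plus an ``is_catch`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

from .stimuli import (
    CausalEvent,
    FeatureSpace,
    GeneralizationTask,
    Stone,
    exp1_space,
    exp2_space,
)

__all__ = ["BehavioralDataset", "read_trials", "write_trials", "SchemaError"]

META_COLUMNS = ("participant_id", "condition", "transfer_order", "trial_index")


class SchemaError(ValueError):
    """A trial table violates the documented schema."""


def _feature_columns(space: FeatureSpace) -> list[str]:
    cols = []
    for role in ("agent", "recipient", "choice"):
        cols += [f"{role}_{f}" for f in space.features]
    return cols


@dataclass
class BehavioralDataset:
    """Per-participant, per-trial chosen outcomes plus condition metadata."""

    trials: pd.DataFrame
    space: FeatureSpace

    def __post_init__(self):
        validate_trials(self.trials, self.space)

    @property
    def n_choices(self) -> int:
        return len(self.scored())

    def scored(self) -> pd.DataFrame:
        """Rows entering model fits (catch trials excluded)."""
        df = self.trials
        if "is_catch" in df.columns:
            return df[~df["is_catch"].astype(bool)]
        return df

    def stone(self, row, role: str) -> Stone:
        return Stone(self.space.features,
                     tuple(row[f"{role}_{f}"] for f in self.space.features))

    def iter_participants(self) -> Iterator[tuple[str, pd.DataFrame]]:
        """Yield (participant_id, rows ordered by trial_index)."""
        for pid, g in self.trials.groupby("participant_id", sort=True):
            yield pid, g.sort_values("trial_index")


def validate_trials(df: pd.DataFrame, space: FeatureSpace) -> None:
    missing = [c for c in META_COLUMNS + tuple(_feature_columns(space))
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    errors = []
    for f in space.features:
        admissible = set(space.values_of(f))
        for role in ("agent", "recipient", "choice"):
            col = f"{role}_{f}"
            bad = ~df[col].isin(admissible)
            for row_no in df.index[bad][:10]:
                errors.append(
                    f"row {row_no}: {col}={df.at[row_no, col]!r} not in "
                    f"{sorted(admissible, key=str)}"
                )
    if errors:
        raise SchemaError("; ".join(errors))


def _infer_space(df: pd.DataFrame) -> FeatureSpace:
    if "agent_color" in df.columns:
        return exp1_space()
    if "agent_shade" in df.columns:
        return exp2_space()
    raise SchemaError("cannot infer the feature space from the columns")


def read_trials(path: str | Path, space: FeatureSpace | None = None) -> BehavioralDataset:
    """Read and validate a trial CSV; schema violations report row numbers."""
    df = pd.read_csv(path)
    if space is None:
        space = _infer_space(df)
    return BehavioralDataset(df, space)


def write_trials(dataset: BehavioralDataset, path: str | Path) -> None:
    dataset.trials.to_csv(path, index=False)


def rows_to_task(row, space: FeatureSpace,
                 panel: tuple[Stone, ...]) -> GeneralizationTask:
    agent = Stone(space.features, tuple(row[f"agent_{f}"] for f in space.features))
    recipient = Stone(space.features,
                      tuple(row[f"recipient_{f}"] for f in space.features))
    is_catch = bool(row["is_catch"]) if "is_catch" in row else False
    return GeneralizationTask(agent, recipient, panel, is_catch=is_catch)
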