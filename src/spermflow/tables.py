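"""In-memory containers for per-cell event and kinematic data."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .config import CHANNEL_MAX


@dataclass
class EventTable:
    """Per-cell scatter/fluorescence measurements for one sample and assay.

    ``data`` holds one column per named channel, values in
    ``[0, channel_max]``.  ``labels`` (optional) carries hidden ground-truth
    component memberships for synthetic data; ``truth`` carries the
    generator's model-implied values of the downstream statistics.
    """

    sample_id: str
    assay: str
    data: pd.DataFrame
    channel_max: float = CHANNEL_MAX
    n_clipped: int = 0
    truth: Mapping[str, Any] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.data) < 1:
            raise ValueError("EventTable needs at least one event")
        if self.data.columns.duplicated().any():
            raise ValueError("channel names must be unique")
        values = self.data.to_numpy(dtype=float)
        if np.any(values < 0) or np.any(values > self.channel_max):
            raise ValueError(
                f"channel values outside [0, {self.channel_max}]"
            )
        if self.labels is not None and len(self.labels) != len(self.data):
            raise ValueError("labels must align with events")

    @property
    def channels(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_events(self) -> int:
        return len(self.data)

    def subset(self, mask: np.ndarray) -> "EventTable":
        """Row subset keeping labels/truth aligned (mask is boolean)."""
        mask = np.asarray(mask, dtype=bool)
        labels = self.labels[mask] if self.labels is not None else None
        return replace(
            self,
            data=self.data.loc[mask].reset_index(drop=True),
            labels=labels,
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        if self.labels is not None:
            df["_component"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        sample_id: str,
        assay: str,
        channel_map: Mapping[str, str] | None = None,
        channel_max: float = CHANNEL_MAX,
    ) -> "EventTable":
        df = pd.read_csv(path)
        labels = None
        if "_component" in df.columns:
            labels = df.pop("_component").to_numpy()
        if channel_map:
            missing = [c for c in channel_map if c not in df.columns]
            if missing:
                raise ValueError(f"channels not found in {path}: {missing}")
            df = df.rename(columns=dict(channel_map))
        return cls(
            sample_id=sample_id,
            assay=assay,
            data=df,
            channel_max=channel_max,
            labels=labels,
        )


#: Canonical CASA column order.
KINEMATIC_COLUMNS = (
    "vcl", "vsl", "vap", "lin", "str", "wob", "alh", "bcf", "dnc", "dncm",
)


@dataclass
class KinematicTable:
    """Per-cell CASA kinematics for one sample (columns as in
    :data:`KINEMATIC_COLUMNS`)."""

    sample_id: str
    data: pd.DataFrame
    truth: Mapping[str, Any] | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing = [c for c in KINEMATIC_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing kinematic columns: {missing}")
        if self.labels is not None and len(self.labels) != len(self.data):
            raise ValueError("labels must align with cells")

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        if self.labels is not None:
            df["_component"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        sample_id: str,
        column_map: Mapping[str, str] | None = None,
    ) -> "KinematicTable":
        df = pd.read_csv(path)
        labels = None
        if "_component" in df.columns:
            labels = df.pop("_component").to_numpy()
        if column_map:
            df = df.rename(columns=dict(column_map))
        return cls(sample_id=sample_id, data=df, labels=labels)
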