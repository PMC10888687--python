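"""Reading and writing event/kinematic tables and report bundles (CSV/JSON)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .tables import EventTable, KinematicTable

__all__ = [
    "read_event_data",
    "write_event_data",
    "read_kinematic_data",
    "write_kinematic_data",
    "write_json",
    "write_study_csv",
]


def read_event_data(
    path: str | Path,
    sample_id: str,
    assay: str,
    channel_map: Mapping[str, str] | None = None,
    channel_max: float = 1023.0,
) -> EventTable:
    """Read a per-cell event CSV (one column per channel).

    ``channel_map`` renames file columns to the canonical channel names
    (``{file_column: canonical_name}``); a mapped column missing from the
    file is an error naming it.  Unmapped columns are preserved (and simply
    ignored by the statistics).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return EventTable.from_csv(
        path, sample_id=sample_id, assay=assay,
        channel_map=channel_map, channel_max=channel_max,
    )


def write_event_data(events: EventTable, path: str | Path) -> None:
    events.to_csv(path)


def read_kinematic_data(
    path: str | Path,
    sample_id: str,
    column_map: Mapping[str, str] | None = None,
) -> KinematicTable:
    """Read a per-cell CASA export CSV (configurable column mapping)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return KinematicTable.from_csv(path, sample_id=sample_id, column_map=column_map)


def write_kinematic_data(table: KinematicTable, path: str | Path) -> None:
    table.to_csv(path)


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(obj: Any):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_study_csv(bundle, out_dir: str | Path) -> None:
    """Write a simulated study to disk: one event CSV per sample x assay,
    one kinematics CSV per sample, plus the design and truth tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.design_table.to_csv(out / "design.csv", index=False)
    bundle.truth_table.to_csv(out / "truth.csv", index=False)
    for (sample_id, assay), table in bundle.events.items():
        table.to_csv(out / f"{sample_id}_{assay}.csv")
    for sample_id, kin in bundle.kinematics.items():
        if kin is not None:
            kin.to_csv(out / f"{sample_id}_CASA.csv")


def read_study_csv(in_dir: str | Path) -> tuple[pd.DataFrame, dict, dict]:
    """Read a study written by :func:`write_study_csv` (or laid out the same
    way): returns (design table, events dict keyed by (sample_id, assay),
    kinematics dict keyed by sample_id)."""
    src = Path(in_dir)
    design = pd.read_csv(src / "design.csv")
    events: dict[tuple[str, str], EventTable] = {}
    kinematics: dict[str, KinematicTable] = {}
    for _, row in design.iterrows():
        sid = row["sample_id"]
        for path in sorted(src.glob(f"{sid}_*.csv")):
            assay = path.stem[len(sid) + 1:]
            if assay == "CASA":
                kinematics[sid] = read_kinematic_data(path, sample_id=sid)
            else:
                events[(sid, assay)] = read_event_data(
                    path, sample_id=sid, assay=assay
                )
    return design, events, kinematics
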