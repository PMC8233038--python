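"""CSV dialects, configuration, and result serialisation.

Three tidy CSV tables carry all on-disk data (comma separator, UTF-8,
header row, '.' decimal; lengths in µm, time in s, time zero at cable
emergence from the bud neck):

* ``trajectories.csv`` — cable_id, cell_id, frame, time_s, length_um
  [, tip_x_um, tip_y_um]
* ``traces.csv`` — cable_id, point_index, x_um, y_um [, z_um]
* ``cells.csv`` — cell_id, strain, length_um, width_um, height_um
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .geometry import CellGeometry
from .trajectory import Trajectory

TRAJECTORY_COLUMNS = ["cable_id", "cell_id", "frame", "time_s", "length_um"]
TRACE_COLUMNS = ["cable_id", "point_index", "x_um", "y_um"]
CELL_COLUMNS = ["cell_id", "strain", "length_um", "width_um", "height_um"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")


def read_cells(path) -> dict[str, CellGeometry]:
    """Read cells.csv into a mapping cell_id → CellGeometry."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, CELL_COLUMNS, f"cells file {path}")
    out: dict[str, CellGeometry] = {}
    for row_no, row in df.iterrows():
        cid = str(row["cell_id"])
        if cid in out:
            raise ValidationError(f"cells file {path}: duplicate cell_id {cid!r} (row {row_no})")
        try:
            out[cid] = CellGeometry(
                float(row["length_um"]),
                float(row["width_um"]),
                float(row["height_um"]),
                strain=str(row["strain"]),
            )
        except ValidationError as exc:
            raise ValidationError(f"cells file {path}, row {row_no}: {exc}") from exc
    return out


def tables_to_trajectories(
    traj_df: pd.DataFrame, cells: pd.DataFrame | dict[str, CellGeometry]
) -> list[Trajectory]:
    """Assemble Trajectory objects from tidy tables (order-independent)."""
    _require_columns(traj_df, TRAJECTORY_COLUMNS, "trajectory table")
    if isinstance(cells, pd.DataFrame):
        cell_map: dict[str, CellGeometry] = {}
        _require_columns(cells, CELL_COLUMNS, "cells table")
        for _, row in cells.iterrows():
            cell_map[str(row["cell_id"])] = CellGeometry(
                float(row["length_um"]),
                float(row["width_um"]),
                float(row["height_um"]),
                strain=str(row["strain"]),
            )
    else:
        cell_map = cells
    df = traj_df.sort_values(["cable_id", "time_s"], kind="stable")
    has_tip = {"tip_x_um", "tip_y_um"}.issubset(df.columns)
    out = []
    for cable_id, grp in df.groupby("cable_id", sort=True):
        cell_ids = grp["cell_id"].astype(str).unique()
        if len(cell_ids) != 1:
            raise ValidationError(
                f"cable {cable_id!r} references multiple cells {list(cell_ids)}"
            )
        cid = cell_ids[0]
        if cid not in cell_map:
            rows = grp.index.tolist()
            raise ValidationError(
                f"cable {cable_id!r} references unknown cell_id {cid!r} (rows {rows[:5]})"
            )
        times = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            bad = grp.index[1:][np.diff(times) <= 0].tolist()
            raise ValidationError(
                f"cable {cable_id!r}: non-increasing time at rows {bad[:5]}"
            )
        tip = grp[["tip_x_um", "tip_y_um"]].to_numpy(dtype=float) if has_tip else None
        out.append(
            Trajectory(
                str(cable_id),
                times,
                grp["length_um"].to_numpy(dtype=float),
                cell_map[cid],
                tip_xy_um=tip,
            )
        )
    return out


def read_traces(path) -> dict[str, np.ndarray]:
    """Read traces.csv into a mapping cable_id → (n, 2|3) coordinate array."""
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, TRACE_COLUMNS, f"traces file {path}")
    cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    out = {}
    for cable_id, grp in df.sort_values(["cable_id", "point_index"], kind="stable").groupby(
        "cable_id", sort=True
    ):
        out[str(cable_id)] = grp[cols].to_numpy(dtype=float)
    return out


def read_tables(
    trajectories=None, traces=None, cells=None
) -> dict:
    """Read any subset of the three dialects; cross-references resolved.

    Returns a dict with keys ``trajectories`` (list of Trajectory),
    ``traces`` (cable_id → coords) and ``cells`` (cell_id → CellGeometry)
    for the inputs provided.
    """
    out: dict = {}
    cell_map = read_cells(cells) if cells is not None else None
    if cell_map is not None:
        out["cells"] = cell_map
    if trajectories is not None:
        if cell_map is None:
            raise ValidationError("trajectories require a cells table for cross-references")
        out["trajectories"] = tables_to_trajectories(
            pd.read_csv(trajectories, float_precision="round_trip"), cell_map
        )
    if traces is not None:
        out["traces"] = read_traces(traces)
    return out


# ---------------------------------------------------------------------------
# writers


def cells_to_frame(
    cells: Sequence[CellGeometry], cell_ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    if cell_ids is None:
        cell_ids = [f"cell{i:04d}" for i in range(len(cells))]
    return pd.DataFrame(
        {
            "cell_id": list(cell_ids),
            "strain": [c.strain for c in cells],
            "length_um": [c.length_um for c in cells],
            "width_um": [c.width_um for c in cells],
            "height_um": [c.height_um for c in cells],
        }
    )


def trajectories_to_frame(
    trajs: Sequence[Trajectory], cell_ids: Sequence[str]
) -> pd.DataFrame:
    if len(cell_ids) != len(trajs):
        raise ValidationError("need one cell_id per trajectory")
    parts = []
    for traj, cid in zip(trajs, cell_ids):
        part = pd.DataFrame(
            {
                "cable_id": traj.cable_id,
                "cell_id": cid,
                "frame": np.arange(traj.n_frames),
                "time_s": traj.times_s,
                "length_um": traj.lengths_um,
            }
        )
        if traj.tip_xy_um is not None:
            part["tip_x_um"] = traj.tip_xy_um[:, 0]
            part["tip_y_um"] = traj.tip_xy_um[:, 1]
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def write_cells(cells, path, cell_ids=None) -> pd.DataFrame:
    df = cells_to_frame(cells, cell_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def write_trajectories(trajs, path, cell_ids) -> pd.DataFrame:
    df = trajectories_to_frame(trajs, cell_ids)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


# ---------------------------------------------------------------------------
# configuration and result provenance


@dataclass
class RunConfig:
    """Serializable settings for one pipeline run."""

    command: str = ""
    seed: int = 0
    family: str = "linear"
    f0: Optional[float] = None
    x_star: Optional[float] = None
    fprime0: Optional[float] = None
    k_dis: Optional[float] = None
    lam: Optional[float] = None
    L_max_ratio: Optional[float] = None
    preset: Optional[str] = None
    n: Optional[int] = None
    cell_length_um: Optional[float] = None
    frame_interval_s: float = 3.0
    duration_s: float = 120.0
    rate_noise_cv: float = 0.3
    tip_noise_sd_um: float = 0.05
    window_s: float = 10.0
    bin_width: float = 0.5
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def write_results_json(payload: dict, path, config: Optional[RunConfig] = None) -> dict:
    """Write a results JSON embedding seed + config hash for provenance."""
    doc = dict(payload)
    if config is not None:
        doc["_provenance"] = {
            "seed": config.seed,
            "config_hash": config.hash(),
            "config": config.to_dict(),
        }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)
        fh.write("\n")
    return doc


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
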