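"""Trajectory containers, CSV I/O, calibration and downsampling.

A trajectory is one worker's body-centre position over a 60-min recording in
a circular arena (wet filter paper, usable diameter 140 mm).  The CSV dialect
is deliberately minimal: header ``frame,x,y``, 0-based frame index, one file
per individual.  Coordinates on disk may be pixels (raw tracker output) or
mm; :func:`read_trajectory` applies a mm-per-pixel calibration and recentres
on the arena centre, so in-memory positions are always mm relative to the
centre.  A study-level metadata CSV carries one row per individual
(individual_id, species, colony, nesting_type, body_length_mm).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ArenaGeometry",
    "Trajectory",
    "ScaleBar",
    "read_trajectory",
    "write_trajectory",
    "read_metadata",
    "write_metadata",
    "downsample",
    "load_config",
]

NESTING_TYPES = ("one_piece", "forager")

METADATA_COLUMNS = ["individual_id", "species", "colony", "nesting_type", "body_length_mm"]


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular arena floor; the inner circle of radius r/sqrt(2) halves the area.

    ``radius_mm`` defaults to 70 (filter paper diameter 140 mm); the
    equal-area inner region is the disc of diameter 140/sqrt(2) mm.
    """

    radius_mm: float = 70.0
    center_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ValueError("arena radius must be positive")

    @property
    def inner_radius_mm(self) -> float:
        return self.radius_mm / math.sqrt(2.0)


@dataclass(frozen=True)
class Trajectory:
    """Calibrated position time series with study metadata.

    ``positions`` is an (n, 2) float array in mm relative to the arena
    centre; ``frame_interval_s`` is the time between consecutive rows.
    """

    individual_id: str
    species: str
    colony: str
    nesting_type: str
    body_length_mm: float
    frame_interval_s: float
    positions: np.ndarray
    arena: ArenaGeometry = field(default_factory=ArenaGeometry)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] == 0:
            raise ValueError("positions must be a non-empty (n, 2) array")
        object.__setattr__(self, "positions", pos)
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be positive")
        if not self.body_length_mm > 0:
            raise ValueError("body_length_mm must be positive")
        if self.nesting_type not in NESTING_TYPES:
            raise ValueError(f"nesting_type must be one of {NESTING_TYPES}")

    @property
    def n_frames(self) -> int:
        return int(self.positions.shape[0])

    @property
    def fps(self) -> float:
        return 1.0 / self.frame_interval_s

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.frame_interval_s


@dataclass(frozen=True)
class ScaleBar:
    """Physical reference object of known length imaged at known pixel span."""

    length_mm: float
    length_px: float

    @property
    def mm_per_px(self) -> float:
        if not (self.length_mm > 0 and self.length_px > 0):
            raise ValueError("scale bar lengths must be positive")
        return self.length_mm / self.length_px


def _calibration_factor(calibration) -> float:
    factor = calibration.mm_per_px if isinstance(calibration, ScaleBar) else float(calibration)
    if not factor > 0:
        raise ValueError("calibration factor must be positive")
    return factor


def read_trajectory(
    path,
    metadata: Mapping[str, object],
    calibration: float | ScaleBar = 1.0,
    center_px: tuple[float, float] = (0.0, 0.0),
    arena: ArenaGeometry | None = None,
    frame_interval_s: float = 0.2,
) -> Trajectory:
    """Read one ``frame,x,y`` CSV, calibrate to mm and centre on the arena.

    ``metadata`` supplies individual_id, species, colony, nesting_type and
    body_length_mm.  Malformed rows (missing columns, non-numeric values,
    non-monotone frame index) are rejected with a row-level message.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file") from None
    missing = [c for c in ("frame", "x", "y") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")
    for col in ("frame", "x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise ValueError(f"{path}: non-numeric {col!r} at data row {bad[0]}")
        df[col] = vals
    frames = df["frame"].to_numpy()
    steps_back = np.flatnonzero(np.diff(frames) <= 0)
    if steps_back.size:
        raise ValueError(f"{path}: frame index not strictly increasing at data row {steps_back[0] + 1}")

    factor = _calibration_factor(calibration)
    cx, cy = center_px
    positions = np.column_stack(
        [(df["x"].to_numpy() - cx) * factor, (df["y"].to_numpy() - cy) * factor]
    )
    return Trajectory(
        individual_id=str(metadata["individual_id"]),
        species=str(metadata["species"]),
        colony=str(metadata["colony"]),
        nesting_type=str(metadata["nesting_type"]),
        body_length_mm=float(metadata["body_length_mm"]),
        frame_interval_s=float(frame_interval_s),
        positions=positions,
        arena=arena or ArenaGeometry(),
    )


def write_trajectory(traj: Trajectory, path) -> Path:
    """Write the ``frame,x,y`` CSV (mm, 6 decimals); round-trips with factor 1."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "frame": np.arange(traj.n_frames),
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if df["individual_id"].duplicated().any():
        dup = df.loc[df["individual_id"].duplicated(), "individual_id"].iloc[0]
        raise ValueError(f"{path}: duplicated individual_id {dup!r}")
    return df


def write_metadata(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.loc[:, METADATA_COLUMNS].to_csv(path, index=False)
    return path


def downsample(traj: Trajectory, target_fps: float) -> Trajectory:
    """Decimate to ``target_fps`` by keeping every k-th frame from frame 0.

    The source rate must be an integer multiple of the target; tracking data
    recorded at 25 fps are reduced to the 5 fps analysis rate this way.
    """
    if not target_fps > 0:
        raise ValueError("target_fps must be positive")
    ratio = traj.fps / target_fps
    k = round(ratio)
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(f"source rate {traj.fps:g} fps is not an integer multiple of {target_fps:g} fps")
    if k == 1:
        return traj
    return replace(traj, positions=traj.positions[::k], frame_interval_s=traj.frame_interval_s * k)


def load_config(path) -> dict:
    """Load a YAML (or JSON; YAML is a superset) analysis configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
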