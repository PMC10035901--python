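"""Reading, validation and calibration of per-frame multi-fly trajectories.

Trajectories arrive as delimited text exported from a video tracker, one row
per fly per frame.  Internally all coordinates are millimetres with the
origin at the arena centre, because every behavioural threshold downstream
(the 4 mm interaction distance) is metric.  Frames are 0-based and ranges
are half-open.  Missing detections are kept as rows with non-finite
coordinates (or absent rows) and are never silently interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from flysin.errors import (
    EmptyInputError,
    FormatError,
    IdentifierError,
    ParameterError,
)

#: Columns a tracking file must provide (``id`` is accepted for ``fly_id``).
REQUIRED_COLUMNS = ("fly_id", "frame", "x", "y")
OPTIONAL_COLUMNS = ("heading", "body_length")


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and calibration of the circular recording arena.

    Parameters
    ----------
    center_x, center_y : float
        Arena centre in the coordinate system of the raw file (mm, or px
        when ``px_per_mm`` is given).
    radius : float
        Arena radius in mm (default 60, i.e. a 120 mm diameter arena).
    fps : float
        Recording frame rate (default 24).
    px_per_mm : float or None
        Calibration scalar; ``None`` means the file is already in mm.
    """

    center_x: float = 0.0
    center_y: float = 0.0
    radius: float = 60.0
    fps: float = 24.0
    px_per_mm: float | None = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"arena radius must be > 0, got {self.radius}")
        if self.fps <= 0:
            raise ParameterError(f"fps must be > 0, got {self.fps}")
        if self.px_per_mm is not None and self.px_per_mm <= 0:
            raise ParameterError(f"px_per_mm must be > 0, got {self.px_per_mm}")


@dataclass
class TrajectoryTable:
    """Per-frame positions of all flies, calibrated to mm, centre-origin.

    ``data`` holds one row per (fly_id, frame) with columns
    ``fly_id, frame, x, y`` and optionally ``heading, body_length``.
    ``n_frames`` is the length of the recording; frames a fly lacks a row
    for, or rows with non-finite coordinates, count as missing.
    """

    data: pd.DataFrame
    arena: ArenaSpec
    n_frames: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_frames == 0 and len(self.data):
            self.n_frames = int(self.data["frame"].max()) + 1

    @property
    def roster(self) -> list:
        """Sorted distinct fly ids."""
        return sorted(self.data["fly_id"].unique())

    @property
    def n_flies(self) -> int:
        return self.data["fly_id"].nunique()

    def has_headings(self) -> bool:
        return "heading" in self.data.columns

    def position_array(self) -> tuple[np.ndarray, list]:
        """Dense ``(n_frames, n_flies, 2)`` position array, NaN where missing.

        Returns the array together with the roster order of its second axis.
        """
        roster = self.roster
        idx = {f: i for i, f in enumerate(roster)}
        pos = np.full((self.n_frames, len(roster), 2), np.nan)
        rows = self.data
        fi = rows["fly_id"].map(idx).to_numpy()
        fr = rows["frame"].to_numpy(dtype=int)
        pos[fr, fi, 0] = rows["x"].to_numpy(dtype=float)
        pos[fr, fi, 1] = rows["y"].to_numpy(dtype=float)
        return pos, roster

    def body_length_by_fly(self) -> dict | None:
        """Mean body length per fly, or None if the column is absent."""
        if "body_length" not in self.data.columns:
            return None
        return self.data.groupby("fly_id")["body_length"].mean().to_dict()


@dataclass(frozen=True)
class ValidationReport:
    """Counts of data-quality violations; purely descriptive."""

    missing_frames: dict
    n_out_of_arena: int
    n_duplicate_keys: int

    @property
    def n_missing_frames(self) -> int:
        return sum(self.missing_frames.values())

    @property
    def clean(self) -> bool:
        return (
            self.n_missing_frames == 0
            and self.n_out_of_arena == 0
            and self.n_duplicate_keys == 0
        )


def read_tracking(path, arena: ArenaSpec) -> TrajectoryTable:
    """Read a delimited tracking export and calibrate it to mm, centre-origin.

    The file must have a header naming at least ``fly_id`` (or ``id``),
    ``frame``, ``x`` and ``y``.  When ``arena.px_per_mm`` is set, raw
    coordinates (and any ``body_length`` column) are divided by it; the
    arena centre is then subtracted so that stored coordinates have their
    origin at the arena centre.  Rows with non-finite coordinates are kept
    and treated as missing detections downstream.
    """
    df = pd.read_csv(path)
    if df.empty and len(df.columns) == 0:
        raise EmptyInputError(f"{path}: no data")
    if "id" in df.columns and "fly_id" not in df.columns:
        df = df.rename(columns={"id": "fly_id"})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if df.empty:
        raise EmptyInputError(f"{path}: header only, no records")

    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep].copy()
    df["frame"] = df["frame"].astype(int)
    if (df["frame"] < 0).any():
        raise FormatError(f"{path}: negative frame indices")

    # centre is given in raw units, so it is calibrated by the same scale
    scale = arena.px_per_mm if arena.px_per_mm is not None else 1.0
    df["x"] = (df["x"].astype(float) - arena.center_x) / scale
    df["y"] = (df["y"].astype(float) - arena.center_y) / scale
    if "body_length" in df.columns:
        df["body_length"] = df["body_length"].astype(float) / scale

    calibrated = replace(arena, center_x=0.0, center_y=0.0, px_per_mm=None)
    df = df.sort_values(["fly_id", "frame"], kind="stable").reset_index(drop=True)
    return TrajectoryTable(data=df, arena=calibrated)


def write_trajectories(traj: TrajectoryTable, path) -> None:
    """Write a table as CSV, inverse of :func:`read_tracking` (identity arena)."""
    if len(traj.data) == 0:
        raise EmptyInputError("nothing to write: empty trajectory table")
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in traj.data.columns]
    traj.data[cols].to_csv(path, index=False)


def validate_trajectories(
    traj: TrajectoryTable, tolerance_mm: float = 2.0
) -> ValidationReport:
    """Report missing frames per fly, out-of-arena points and duplicate keys.

    A point is out of arena when its distance from the centre exceeds the
    arena radius plus ``tolerance_mm`` (one body length by default: the
    tracked centroid of a wall-climbing fly may fall marginally outside).
    """
    df = traj.data
    n_dup = int(df.duplicated(subset=["fly_id", "frame"]).sum())

    missing: dict = {}
    finite = np.isfinite(df["x"].to_numpy()) & np.isfinite(df["y"].to_numpy())
    for fly, grp in df.groupby("fly_id"):
        present = grp.loc[finite[grp.index], "frame"].nunique()
        missing[fly] = traj.n_frames - present

    r = np.hypot(df["x"].to_numpy(), df["y"].to_numpy())
    n_out = int(np.sum(finite & (r > traj.arena.radius + tolerance_mm)))
    return ValidationReport(
        missing_frames=missing, n_out_of_arena=n_out, n_duplicate_keys=n_dup
    )


def pairwise_distance_series(traj: TrajectoryTable, a, b) -> np.ndarray:
    """Per-frame centroid distance (mm) between flies ``a`` and ``b``.

    Length equals ``n_frames``; NaN wherever either fly is missing.
    Symmetric in (a, b).
    """
    if a == b:
        raise IdentifierError(f"need two distinct flies, got '{a}' twice")
    roster = traj.roster
    for fly in (a, b):
        if fly not in roster:
            raise IdentifierError(f"unknown fly id '{fly}'")
    pos, order = traj.position_array()
    ia, ib = order.index(a), order.index(b)
    delta = pos[:, ia, :] - pos[:, ib, :]
    return np.hypot(delta[:, 0], delta[:, 1])


def interpolate_gaps(traj: TrajectoryTable, max_gap: int = 3) -> TrajectoryTable:
    """Linearly fill missing-coordinate gaps of at most ``max_gap`` frames.

    Off the default pipeline path: provided for trackers that drop single
    frames, never applied implicitly.
    """
    if max_gap < 1:
        raise ParameterError(f"max_gap must be >= 1, got {max_gap}")
    frames = np.arange(traj.n_frames)
    out = []
    for fly, grp in traj.data.groupby("fly_id"):
        g = (
            grp.set_index("frame")
            .reindex(frames)
            .assign(fly_id=fly)
            .rename_axis("frame")
            .reset_index()
        )
        # fill a gap only when it is short enough, never partially
        missing = g["x"].isna() | g["y"].isna()
        run_id = (missing != missing.shift()).cumsum()
        run_len = missing.groupby(run_id).transform("size")
        fillable = missing & (run_len <= max_gap)
        for col in ("x", "y"):
            filled = g[col].interpolate(limit_area="inside")
            g.loc[fillable, col] = filled[fillable]
        out.append(g.dropna(subset=["x", "y"]))
    df = pd.concat(out, ignore_index=True)
    cols = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in traj.data.columns]
    df = df[cols].sort_values(["fly_id", "frame"], kind="stable").reset_index(drop=True)
    return TrajectoryTable(data=df, arena=traj.arena, n_frames=traj.n_frames)
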