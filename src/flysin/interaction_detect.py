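"""Pairwise interaction detection from calibrated trajectories.

An interaction is a continuous episode in which two flies stay within a
distance threshold of each other — two body lengths, 4 mm by default — for
at least a minimum duration, 0.5 s by default (12 frames at 24 fps).  The
minimum is applied inclusively (>= 0.5 s) and per episode, not cumulatively
per pair.  Frames where either fly is undetected terminate an episode and
are never bridged; an optional gap tolerance can fuse episodes separated by
short above-threshold excursions, for trackers that jitter across the
distance boundary, but defaults to zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from flysin.errors import ParameterError
from flysin.trajectory_io import TrajectoryTable


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance/duration criteria defining a social interaction.

    distance_threshold_bl : threshold in body lengths (default 2).
    body_length_mm : nominal fly body length (default 2.0 mm); overridden
        per pair by the mean of the two flies' tracked body lengths when a
        ``body_length`` column is present.
    min_duration_s : minimum episode duration in seconds, inclusive.
    gap_tolerance_frames : above-threshold gap length (frames) fused into a
        single episode; 0 disables fusion.
    """

    distance_threshold_bl: float = 2.0
    body_length_mm: float = 2.0
    min_duration_s: float = 0.5
    gap_tolerance_frames: int = 0

    def __post_init__(self) -> None:
        if self.distance_threshold_bl <= 0:
            raise ParameterError("distance_threshold_bl must be > 0")
        if self.body_length_mm <= 0:
            raise ParameterError("body_length_mm must be > 0")
        if self.min_duration_s <= 0:
            raise ParameterError("min_duration_s must be > 0")
        if self.gap_tolerance_frames < 0:
            raise ParameterError("gap_tolerance_frames must be >= 0")

    @property
    def distance_threshold_mm(self) -> float:
        """Effective metric threshold (default 2 x 2.0 = 4 mm)."""
        return self.distance_threshold_bl * self.body_length_mm


@dataclass(frozen=True, order=True)
class InteractionEvent:
    """One proximity episode between an unordered fly pair.

    ``fly_a < fly_b`` under the ids' natural order; ``[start_frame,
    end_frame)`` is half-open; ``duration_s = (end - start) / fps``.
    """

    fly_a: object
    fly_b: object
    start_frame: int
    end_frame: int
    duration_s: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) index ranges of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def _fuse_runs(
    runs: list[tuple[int, int]], gap: int, blocked: np.ndarray
) -> list[tuple[int, int]]:
    """Fuse runs separated by <= gap frames, unless the gap contains a
    blocked (missing-detection) frame."""
    if gap <= 0 or len(runs) < 2:
        return runs
    fused = [runs[0]]
    for start, end in runs[1:]:
        p_start, p_end = fused[-1]
        if start - p_end <= gap and not blocked[p_end:start].any():
            fused[-1] = (p_start, end)
        else:
            fused.append((start, end))
    return fused


def detect_events(
    traj: TrajectoryTable, criteria: InteractionCriteria | None = None
) -> list[InteractionEvent]:
    """Extract all interaction events from a trajectory table.

    For every unordered pair of flies, maximal runs of frames with distance
    at or below the threshold are found (gap-fused per
    ``criteria.gap_tolerance_frames``) and emitted as events iff their
    duration reaches ``criteria.min_duration_s``.  Output is sorted by
    (fly_a, fly_b, start_frame).
    """
    if criteria is None:
        criteria = InteractionCriteria()
    pos, roster = traj.position_array()
    fps = traj.arena.fps
    min_frames = int(np.ceil(criteria.min_duration_s * fps))
    body = traj.body_length_by_fly()

    events: list[InteractionEvent] = []
    for ia, ib in itertools.combinations(range(len(roster)), 2):
        delta = pos[:, ia, :] - pos[:, ib, :]
        dist = np.hypot(delta[:, 0], delta[:, 1])
        missing = ~np.isfinite(dist)
        if body is not None:
            bl = (body[roster[ia]] + body[roster[ib]]) / 2.0
            thr = criteria.distance_threshold_bl * bl
        else:
            thr = criteria.distance_threshold_mm
        with np.errstate(invalid="ignore"):
            close = np.where(missing, False, dist <= thr)
        runs = _fuse_runs(_runs(close), criteria.gap_tolerance_frames, missing)
        for start, end in runs:
            if end - start >= min_frames:
                events.append(
                    InteractionEvent(
                        roster[ia], roster[ib], start, end, (end - start) / fps
                    )
                )
    events.sort(key=lambda e: (str(e.fly_a), str(e.fly_b), e.start_frame))
    return events


def merge_events(
    events: list[InteractionEvent], gap_tolerance_frames: int, fps: float = 24.0
) -> list[InteractionEvent]:
    """Fuse events of the same pair separated by <= ``gap_tolerance_frames``.

    Durations are recomputed from the fused frame range.  Idempotent;
    tolerance 0 returns the input unchanged.
    """
    if gap_tolerance_frames < 0:
        raise ParameterError("gap_tolerance_frames must be >= 0")
    if gap_tolerance_frames == 0 or not events:
        return list(events)
    out: list[InteractionEvent] = []
    key = lambda e: (str(e.fly_a), str(e.fly_b))
    for _, group in itertools.groupby(sorted(events, key=lambda e: (str(e.fly_a), str(e.fly_b), e.start_frame)), key=key):
        group = list(group)
        cur = group[0]
        for nxt in group[1:]:
            if nxt.start_frame - cur.end_frame <= gap_tolerance_frames:
                cur = InteractionEvent(
                    cur.fly_a,
                    cur.fly_b,
                    cur.start_frame,
                    nxt.end_frame,
                    (nxt.end_frame - cur.start_frame) / fps,
                )
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    return out


def events_summary(events: list[InteractionEvent]) -> tuple[pd.DataFrame, dict]:
    """Per-pair interaction count and total duration, plus population totals.

    Returns a DataFrame with columns ``fly_a, fly_b, n_events,
    total_duration_s`` (one row per interacting pair) and a dict with keys
    ``n_events`` and ``total_duration_s`` summed over all pairs.
    """
    if not events:
        empty = pd.DataFrame(
            columns=["fly_a", "fly_b", "n_events", "total_duration_s"]
        )
        return empty, {"n_events": 0, "total_duration_s": 0.0}
    df = pd.DataFrame(
        {
            "fly_a": [e.fly_a for e in events],
            "fly_b": [e.fly_b for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    )
    per_pair = (
        df.groupby(["fly_a", "fly_b"], sort=True)["duration_s"]
        .agg(n_events="count", total_duration_s="sum")
        .reset_index()
    )
    totals = {
        "n_events": int(per_pair["n_events"].sum()),
        "total_duration_s": float(per_pair["total_duration_s"].sum()),
    }
    return per_pair, totals


def write_events(events: list[InteractionEvent], path) -> None:
    """Write events as CSV ``fly_a,fly_b,start_frame,end_frame,duration_s``."""
    pd.DataFrame(
        [
            (e.fly_a, e.fly_b, e.start_frame, e.end_frame, e.duration_s)
            for e in events
        ],
        columns=["fly_a", "fly_b", "start_frame", "end_frame", "duration_s"],
    ).to_csv(path, index=False)


def read_events(path) -> list[InteractionEvent]:
    """Read events written by :func:`write_events`."""
    df = pd.read_csv(path)
    return [
        InteractionEvent(
            r.fly_a, r.fly_b, int(r.start_frame), int(r.end_frame), float(r.duration_s)
        )
        for r in df.itertuples()
    ]
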