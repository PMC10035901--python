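import numpy as np
import pandas as pd
import pytest

from flysin.trajectory_io import ArenaSpec, TrajectoryTable


def make_traj(positions: dict, fps: float = 24.0, radius: float = 60.0,
              body_length: dict | None = None) -> TrajectoryTable:
    """Build a TrajectoryTable from {fly_id: [(x, y) or None per frame]}.

    None marks a missing detection (row omitted).
    """
    rows = []
    n_frames = max(len(v) for v in positions.values())
    for fly, pts in positions.items():
        for f, pt in enumerate(pts):
            if pt is None:
                continue
            row = {"fly_id": fly, "frame": f, "x": pt[0], "y": pt[1]}
            if body_length is not None:
                row["body_length"] = body_length[fly]
            rows.append(row)
    df = pd.DataFrame(rows)
    arena = ArenaSpec(radius=radius, fps=fps)
    return TrajectoryTable(data=df, arena=arena, n_frames=n_frames)


def random_traj(rng: np.random.Generator, n_flies: int = 5, n_frames: int = 200,
                radius: float = 30.0, fps: float = 24.0,
                missing_prob: float = 0.0) -> TrajectoryTable:
    """Random-walk trajectories dense enough to cross the 4 mm threshold."""
    positions = {}
    for i in range(n_flies):
        p = rng.uniform(-radius / 3, radius / 3, size=2)
        pts = []
        for _ in range(n_frames):
            p = p + rng.normal(0, 1.2, size=2)
            r = np.hypot(*p)
            if r > radius:
                p = p * (2 * radius - r) / r
            pts.append(None if rng.uniform() < missing_prob else tuple(p))
        positions[f"f{i}"] = pts
    return make_traj(positions, fps=fps, radius=radius)


@pytest.fixture
def two_fly_traj():
    """Two flies 3 mm apart for 24 frames: one interaction of exactly 1 s."""
    return make_traj({"a": [(0.0, 0.0)] * 24, "b": [(3.0, 0.0)] * 24})


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
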