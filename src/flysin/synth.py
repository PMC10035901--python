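"""Synthetic arena simulator and canonical graph fixtures.

The simulator emulates what a video tracker would export for a group of
~30 flies walking in a 120 mm circular arena filmed at 24 fps for 10
minutes: a correlated random walk per fly with a wall-ward bias
(thigmotaxis), a bounded heading attraction toward flies within a
perception radius, pausing (dwell) that lengthens when another fly is
near, and a configurable fraction of immobile flies that never move —
emulating the isolated, non-interacting individuals seen in drug-fed
groups.  Attraction biases the heading rather than applying a force, so
speeds stay stationary and interaction statistics remain interpretable.
All randomness flows from one seeded generator, so a (config, seed) pair
is fully reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import networkx as nx

from flysin.errors import ParameterError
from flysin.trajectory_io import ArenaSpec, TrajectoryTable


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of one simulated recording.

    Speeds are mm/frame (0.4 mm/frame is ~10 mm/s at 24 fps, a typical
    walking speed).  ``heading_persistence`` in [0,1] weights the previous
    heading; ``thigmotaxis_bias`` in [0,1] pulls toward the wall;
    ``attraction`` biases the heading toward the centroid of flies within
    ``perception_radius_mm``; ``avoidance`` pushes away from the nearest
    one.  Avoidance dominating by default reproduces the social spacing
    walking flies keep (about two body lengths), so drive-pasts rarely
    linger inside the interaction distance.

    Walking flies alternate between rest and walk bouts, as real flies do.
    ``pause_prob`` is the long-run fraction of time spent resting when no
    other fly is nearby; solitary rest bouts have geometric length with
    mean ``mean_pause_s`` seconds and the entry rate is derived from that
    stationary fraction.  ``pause_prob_near`` is different in kind: the
    per-frame probability that a walking fly with another fly inside its
    perception radius approaches it to within ``contact_distance_mm`` and
    sits (a social dwell, geometric with mean ``mean_dwell_s`` seconds) —
    at the default walking speed a mere drive-past stays under the
    minimum interaction duration, so these dwells are what creates
    interaction events.  After every rest or
    dwell the fly walks for at least ``refractory_s`` seconds ignoring
    attraction, so dwelling flies separate again instead of locking into
    permanent clusters.  ``immobile_fraction`` of the flies never move at
    all.  Initial positions are uniform in the disc with a minimum
    separation of ``init_min_separation_mm``.
    """

    n_flies: int = 30
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    duration_s: float = 600.0
    step_speed_mean: float = 0.8
    step_speed_sd: float = 0.15
    heading_persistence: float = 0.85
    thigmotaxis_bias: float = 0.15
    attraction: float = 0.2
    avoidance: float = 1.2
    perception_radius_mm: float = 8.0
    contact_distance_mm: float = 2.5
    pause_prob: float = 0.9
    pause_prob_near: float = 0.03
    mean_pause_s: float = 30.0
    mean_dwell_s: float = 2.0
    refractory_s: float = 1.5
    immobile_fraction: float = 0.0
    init_min_separation_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ParameterError("n_flies must be >= 1")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")
        for name in ("heading_persistence", "thigmotaxis_bias", "pause_prob",
                     "immobile_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.pause_prob_near <= 1.0:
            raise ParameterError("pause_prob_near must be in [0, 1]")
        if self.attraction < 0 or self.avoidance < 0:
            raise ParameterError("attraction and avoidance must be >= 0")
        if self.perception_radius_mm <= 0:
            raise ParameterError("perception_radius_mm must be > 0")
        if not 0 < self.contact_distance_mm <= self.perception_radius_mm:
            raise ParameterError(
                "contact_distance_mm must be in (0, perception_radius_mm]"
            )
        if self.mean_pause_s <= 0 or self.mean_dwell_s <= 0:
            raise ParameterError("mean_pause_s and mean_dwell_s must be > 0")
        if self.refractory_s < 0:
            raise ParameterError("refractory_s must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.arena.fps))

    def _bout_rates(self) -> tuple[float, float, float]:
        """Per-frame (solitary-rest-exit, dwell-exit, solitary-rest-entry)
        rates realising ``pause_prob`` / ``mean_pause_s`` /
        ``mean_dwell_s`` with geometric bouts."""
        q_exit = min(1.0, 1.0 / (self.mean_pause_s * self.arena.fps))
        q_exit_dwell = min(1.0, 1.0 / (self.mean_dwell_s * self.arena.fps))
        if self.pause_prob >= 1.0:
            q_enter = 1.0
        else:
            q_enter = min(1.0, q_exit * self.pause_prob / (1.0 - self.pause_prob))
        return q_exit, q_exit_dwell, q_enter


def _initial_positions(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Uniform in the disc, rejection-sampled for minimum separation."""
    radius = cfg.arena.radius * 0.95
    pos = np.empty((cfg.n_flies, 2))
    placed = 0
    min_sep2 = cfg.init_min_separation_mm**2
    attempts = 0
    while placed < cfg.n_flies:
        r = radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0, 2 * np.pi)
        cand = np.array([r * np.cos(phi), r * np.sin(phi)])
        attempts += 1
        if placed == 0 or (
            ((pos[:placed] - cand) ** 2).sum(axis=1).min() >= min_sep2
        ):
            pos[placed] = cand
            placed += 1
        elif attempts > 10000 * cfg.n_flies:
            raise ParameterError(
                "cannot place flies with the requested minimum separation"
            )
    return pos


def _integrate(
    pos0: np.ndarray,
    theta0: np.ndarray,
    immobile: np.ndarray,
    resting0: np.ndarray,
    noise: np.ndarray,
    pause_u: np.ndarray,
    speed: np.ndarray,
    persistence: float,
    thigmotaxis: float,
    attraction: float,
    avoidance: float,
    perception2: float,
    contact2: float,
    q_exit: float,
    q_exit_dwell: float,
    q_enter: float,
    p_stop_near: float,
    refractory_frames: int,
    radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic core of the walk given pre-drawn random numbers.

    Each mobile fly is in one of three states.  WALK: steer by persistence
    + thigmotaxis (outward, scaled r/R) + attraction toward the local
    centroid of perceived flies - avoidance away from the nearest one +
    noise, and advance by the drawn speed; with a neighbour inside the perception
    radius, begin a social dwell with probability ``p_stop_near`` per
    frame.  APPROACH: head for the nearest perceived fly at walking speed
    until within contact distance, then REST (dwell exit rate
    ``q_exit_dwell``); abort if no fly remains in perception.  Away from
    others a walking fly enters solitary REST at rate ``q_enter`` (exit
    ``q_exit``).  After any rest the fly walks for ``refractory_frames``
    ignoring other flies, so dwell partners separate again.  Overshoot
    past the wall is folded back inside the disc.
    """
    WALK, APPROACH, REST = 0, 1, 2
    n_frames, n = pause_u.shape
    out = np.empty((n_frames, n, 2))
    out_theta = np.empty((n_frames, n))
    pos = pos0.copy()
    theta = theta0.copy()
    new_pos = pos0.copy()
    new_theta = theta0.copy()
    state = np.zeros(n, dtype=np.int8)
    for i in range(n):
        if resting0[i]:
            state[i] = REST
    dwelling = np.zeros(n, dtype=np.bool_)
    refract = np.zeros(n, dtype=np.int64)
    for t in range(n_frames):
        out[t] = pos
        out_theta[t] = theta
        for i in range(n):
            if immobile[i]:
                new_pos[i] = pos[i]
                new_theta[i] = theta[i]
                continue
            # perceived neighbours: centroid, count, nearest
            cx = 0.0
            cy = 0.0
            cnt = 0
            dmin = 1e30
            jmin = -1
            for j in range(n):
                if j == i:
                    continue
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                d2 = dx * dx + dy * dy
                if d2 <= perception2:
                    cx += pos[j, 0]
                    cy += pos[j, 1]
                    cnt += 1
                    if d2 < dmin:
                        dmin = d2
                        jmin = j
            if state[i] == REST:
                qx = q_exit_dwell if dwelling[i] else q_exit
                if pause_u[t, i] < qx:
                    state[i] = WALK
                    dwelling[i] = False
                    refract[i] = refractory_frames
                new_pos[i] = pos[i]
                new_theta[i] = theta[i]
                continue
            if state[i] == APPROACH:
                if cnt == 0:  # lost the target; give up and move on
                    state[i] = WALK
                    refract[i] = refractory_frames
                elif dmin <= contact2:
                    state[i] = REST
                    dwelling[i] = True
                    new_pos[i] = pos[i]
                    new_theta[i] = theta[i]
                    continue
                else:  # head straight for the nearest fly
                    tx = pos[jmin, 0] - pos[i, 0]
                    ty = pos[jmin, 1] - pos[i, 1]
                    tn = np.hypot(tx, ty)
                    th = np.arctan2(ty, tx)
                    sp = min(speed[t, i], tn - 0.5 * np.sqrt(contact2))
                    if sp < 0.0:
                        sp = 0.0
                    px = pos[i, 0] + sp * np.cos(th)
                    py = pos[i, 1] + sp * np.sin(th)
                    new_pos[i, 0] = px
                    new_pos[i, 1] = py
                    new_theta[i] = th
                    continue
            # WALK state
            if refract[i] > 0:
                refract[i] -= 1
                cnt = 0  # departure: ignore neighbours while refractory
            elif cnt > 0:
                if pause_u[t, i] < p_stop_near:
                    state[i] = APPROACH
                    new_pos[i] = pos[i]
                    new_theta[i] = theta[i]
                    continue
            elif pause_u[t, i] < q_enter:
                state[i] = REST
                new_pos[i] = pos[i]
                new_theta[i] = theta[i]
                continue
            # steer and step
            vx = persistence * np.cos(theta[i]) + noise[t, i, 0]
            vy = persistence * np.sin(theta[i]) + noise[t, i, 1]
            r = np.hypot(pos[i, 0], pos[i, 1])
            if r > 1e-9:
                pull = thigmotaxis * (r / radius) / r
                vx += pull * pos[i, 0]
                vy += pull * pos[i, 1]
            if cnt > 0:
                if attraction > 0.0:  # pull toward the local centroid
                    tx = cx / cnt - pos[i, 0]
                    ty = cy / cnt - pos[i, 1]
                    tn = np.hypot(tx, ty)
                    if tn > 1e-9:
                        vx += attraction * tx / tn
                        vy += attraction * ty / tn
                if avoidance > 0.0:  # push away from the nearest fly
                    tx = pos[jmin, 0] - pos[i, 0]
                    ty = pos[jmin, 1] - pos[i, 1]
                    tn = np.hypot(tx, ty)
                    if tn > 1e-9:
                        vx -= avoidance * tx / tn
                        vy -= avoidance * ty / tn
            if np.hypot(vx, vy) > 1e-9:
                th = np.arctan2(vy, vx)
            else:
                th = theta[i]
            sp = speed[t, i]
            px = pos[i, 0] + sp * np.cos(th)
            py = pos[i, 1] + sp * np.sin(th)
            rr = np.hypot(px, py)
            if rr > radius:
                scale = (2.0 * radius - rr) / rr
                if scale < 0.0:
                    scale = 0.0
                px *= scale
                py *= scale
                mx = px - pos[i, 0]
                my = py - pos[i, 1]
                if np.hypot(mx, my) > 1e-9:
                    th = np.arctan2(my, mx)
            new_pos[i, 0] = px
            new_pos[i, 1] = py
            new_theta[i] = th
        pos, new_pos = new_pos, pos
        theta, new_theta = new_theta, theta
    return out, out_theta


try:  # optional JIT: identical semantics, ~100x faster integration
    from numba import njit

    _integrate_fast = njit(cache=False)(_integrate)
except ImportError:  # pragma: no cover
    _integrate_fast = _integrate


def simulate_arena(config: SimConfig, jit: bool = True) -> TrajectoryTable:
    """Run the correlated-random-walk simulation; returns a trajectory
    table identical in shape to a calibrated tracker export (with a
    ``heading`` column).  Positions always satisfy x^2 + y^2 <= radius^2.
    Fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, n_frames = config.n_flies, config.n_frames
    radius = config.arena.radius

    pos0 = _initial_positions(rng, config)
    theta0 = rng.uniform(0, 2 * np.pi, size=n)
    n_immobile = int(round(config.immobile_fraction * n))
    immobile = np.zeros(n, dtype=bool)
    immobile[rng.permutation(n)[:n_immobile]] = True
    resting0 = rng.uniform(size=n) < config.pause_prob

    noise = rng.normal(size=(n_frames, n, 2)) * (1.0 - config.heading_persistence)
    pause_u = rng.uniform(size=(n_frames, n))
    speed = np.clip(
        rng.normal(config.step_speed_mean, config.step_speed_sd, size=(n_frames, n)),
        0.0,
        None,
    )
    q_exit, q_exit_dwell, q_enter = config._bout_rates()
    integrate = _integrate_fast if jit else _integrate
    out, out_theta = integrate(
        pos0,
        theta0,
        immobile,
        resting0,
        noise,
        pause_u,
        speed,
        config.heading_persistence,
        config.thigmotaxis_bias,
        config.attraction,
        config.avoidance,
        config.perception_radius_mm**2,
        config.contact_distance_mm**2,
        q_exit,
        q_exit_dwell,
        q_enter,
        config.pause_prob_near,
        int(round(config.refractory_s * config.arena.fps)),
        radius,
    )

    ids = [f"fly{i:02d}" for i in range(n)]
    frames = np.arange(n_frames)
    df = pd.DataFrame(
        {
            "fly_id": np.repeat(ids, n_frames),
            "frame": np.tile(frames, n),
            "x": out[:, :, 0].T.ravel(),
            "y": out[:, :, 1].T.ravel(),
            "heading": out_theta.T.ravel(),
        }
    )
    arena = replace(config.arena, center_x=0.0, center_y=0.0, px_per_mm=None)
    return TrajectoryTable(data=df, arena=arena, n_frames=n_frames)


def preset(name: str) -> SimConfig:
    """Named population configurations.

    ``ctrl_like`` emulates an untreated group: moderate social attraction,
    moderate dwell, almost no immobile flies.  ``coc_like`` emulates a
    psychostimulant-fed group: stronger attraction, much longer dwell near
    other flies, and a larger fraction of immobile (isolated) individuals.
    """
    if name == "ctrl_like":
        return SimConfig(
            attraction=0.2,
            pause_prob=0.9,
            pause_prob_near=0.005,
            mean_dwell_s=2.0,
            immobile_fraction=0.05,
        )
    if name == "coc_like":
        return SimConfig(
            attraction=0.6,
            pause_prob=0.82,
            pause_prob_near=0.018,
            mean_dwell_s=5.0,
            immobile_fraction=0.25,
        )
    raise ParameterError(f"unknown preset '{name}'; expected ctrl_like|coc_like")


def graph_fixture(name: str, n: int = 8, p: float = 0.3, seed: int = 0) -> nx.Graph:
    """Canonical unit-weight SIN fixtures for oracle tests.

    Known names: ``path3, star5, k3, k5, two_triangles, k5_plus_isolates,
    random`` (Erdos-Renyi G(n, p) with the given seed).
    """
    if name == "path3":
        g = nx.path_graph(3)
    elif name == "star5":
        g = nx.star_graph(4)  # 5 nodes: hub + 4 leaves
    elif name == "k3":
        g = nx.complete_graph(3)
    elif name == "k5":
        g = nx.complete_graph(5)
    elif name == "two_triangles":
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    elif name == "k5_plus_isolates":
        g = nx.complete_graph(5)
        g.add_nodes_from(range(5, 10))
    elif name == "random":
        g = nx.gnp_random_graph(n, p, seed=seed)
    else:
        raise ParameterError(f"unknown graph fixture '{name}'")
    sin = nx.Graph(label=name, condition="fixture")
    sin.add_nodes_from(g.nodes)
    for a, b in g.edges:
        sin.add_edge(a, b, w_count=1, w_duration=1.0)
    return sin
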