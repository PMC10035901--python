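"""Independent brute-force reference implementations.

Everything here works from first principles — hand-rolled BFS, exhaustive
shortest-path enumeration, direct formula evaluation on dense matrices —
and never calls the package's measure functions, so agreement is a real
cross-check rather than a tautology.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def adjacency(graph) -> dict:
    """Plain dict-of-sets adjacency from any networkx-like graph."""
    adj = {n: set() for n in graph.nodes}
    for a, b in graph.edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def bfs_distances(adj: dict, source) -> dict:
    dist = {source: 0}
    q = deque([source])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def components(adj: dict) -> list[set]:
    seen: set = set()
    comps = []
    for n in adj:
        if n not in seen:
            comp = set(bfs_distances(adj, n))
            comps.append(comp)
            seen |= comp
    return comps


def largest_component(adj: dict) -> set:
    """Same tie-break rule as the package: size, then smallest node id."""
    comps = sorted(components(adj), key=lambda c: (-len(c), min(str(n) for n in c)))
    return comps[0] if comps else set()


def restrict(adj: dict, nodes: set) -> dict:
    return {n: adj[n] & nodes for n in nodes}


def all_shortest_paths(adj: dict, s, t) -> list[list]:
    """Every shortest s-t path, via BFS predecessor DAG enumeration."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths = []

    def backtrack(node, acc):
        if node == s:
            paths.append([s] + acc)
            return
        for p in adj[node]:
            if p in dist and dist[p] == dist[node] - 1:
                backtrack(p, [node] + acc)

    backtrack(t, [])
    return paths


def oracle_degree_centrality(graph) -> dict:
    adj = adjacency(graph)
    n = len(adj)
    return {v: len(adj[v]) / (n - 1) for v in adj}


def oracle_closeness(graph) -> dict:
    """Normalised closeness on the largest component, 0 outside."""
    adj = adjacency(graph)
    comp = largest_component(adj)
    sub = restrict(adj, comp)
    out = {v: 0.0 for v in adj}
    if len(comp) < 2:
        return out
    for v in comp:
        total = sum(d for u, d in bfs_distances(sub, v).items() if u != v)
        out[v] = (len(comp) - 1) / total if total else 0.0
    return out


def oracle_betweenness(graph) -> dict:
    """Betweenness by exhaustive shortest-path enumeration, normalised by
    (N-1)(N-2) ordered pairs of the largest component; 0 outside."""
    adj = adjacency(graph)
    comp = largest_component(adj)
    sub = restrict(adj, comp)
    out = {v: 0.0 for v in adj}
    n = len(comp)
    if n < 3:
        return out
    for s, t in itertools.combinations(sorted(comp, key=str), 2):
        paths = all_shortest_paths(sub, s, t)
        if not paths:
            continue
        for v in comp:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            out[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2.0  # unordered pairs; Eq uses both orientations
    for v in comp:
        out[v] /= norm
    return out


def oracle_local_clustering(graph) -> dict:
    adj = adjacency(graph)
    out = {}
    for v in adj:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def oracle_information_centrality(graph) -> dict:
    """1 / (total effective resistance to all other nodes), computed from
    the Laplacian pseudoinverse of the largest component; 0 outside."""
    adj = adjacency(graph)
    comp = sorted(largest_component(adj), key=str)
    out = {v: 0.0 for v in adj}
    if len(comp) < 2:
        return out
    index = {v: i for i, v in enumerate(comp)}
    lap = np.zeros((len(comp), len(comp)))
    for v in comp:
        for u in adj[v] & set(comp):
            lap[index[v], index[u]] = -1.0
        lap[index[v], index[v]] = len(adj[v] & set(comp))
    pinv = np.linalg.pinv(lap)
    for v in comp:
        i = index[v]
        total_r = sum(
            pinv[i, i] + pinv[j, j] - 2 * pinv[i, j]
            for j in range(len(comp))
            if j != i
        )
        out[v] = 1.0 / total_r
    return out


def oracle_eigenvector(graph, iterations: int = 50000, tol: float = 1e-13) -> dict:
    """Power iteration on the dense adjacency of the largest component."""
    adj = adjacency(graph)
    comp = sorted(largest_component(adj), key=str)
    out = {v: 0.0 for v in adj}
    if len(comp) < 2:
        return out
    index = {v: i for i, v in enumerate(comp)}
    a = np.zeros((len(comp), len(comp)))
    for v in comp:
        for u in adj[v] & set(comp):
            a[index[v], index[u]] = 1.0
    x = np.ones(len(comp)) / np.sqrt(len(comp))
    for _ in range(iterations):
        y = x + a @ x  # shift by +I: breaks bipartite eigenvalue ties
        norm = np.linalg.norm(y)
        if norm == 0:
            break
        y /= norm
        if np.abs(y - x).sum() < tol:
            x = y
            break
        x = y
    for v in comp:
        out[v] = abs(x[index[v]])
    return out


# ---- global measures -------------------------------------------------------


def oracle_avg_shortest_path(graph) -> float:
    adj = adjacency(graph)
    comp = largest_component(adj)
    sub = restrict(adj, comp)
    if len(comp) < 2:
        return float("nan")
    total = 0
    for v in comp:
        total += sum(d for u, d in bfs_distances(sub, v).items() if u != v)
    return total / (len(comp) * (len(comp) - 1))


def oracle_diameter(graph) -> float:
    adj = adjacency(graph)
    comp = largest_component(adj)
    sub = restrict(adj, comp)
    if len(comp) < 2:
        return float("nan")
    return float(
        max(max(bfs_distances(sub, v).values()) for v in comp)
    )


def oracle_global_efficiency(graph) -> float:
    adj = adjacency(graph)
    comp = largest_component(adj)
    sub = restrict(adj, comp)
    if len(comp) < 2:
        return float("nan")
    total = 0.0
    for v in comp:
        total += sum(1.0 / d for u, d in bfs_distances(sub, v).items() if u != v)
    return total / (len(comp) * (len(comp) - 1))


def oracle_density(graph) -> float:
    n = graph.number_of_nodes()
    k = graph.number_of_edges()
    return 2.0 * k / (n * (n - 1)) if n >= 2 else float("nan")


def oracle_transitivity(graph) -> float:
    adj = adjacency(graph)
    triangles = 0
    triads = 0
    for v in adj:
        k = len(adj[v])
        triads += k * (k - 1) // 2
        triangles += sum(
            1 for a, b in itertools.combinations(adj[v], 2) if b in adj[a]
        )
    # per-vertex triangle counts already sum to 3 x #triangles
    return triangles / triads if triads else 0.0


def oracle_heterogeneity(graph) -> float:
    degs = np.array([len(v) for v in adjacency(graph).values()], dtype=float)
    if degs.size == 0 or degs.mean() == 0:
        return float("nan")
    return float(degs.std() / degs.mean())


def oracle_assortativity(graph) -> float:
    """Pearson correlation of excess degrees over edge endpoints, both
    orientations, from the raw value lists."""
    adj = adjacency(graph)
    xs, ys = [], []
    for a, b in graph.edges:
        xs += [len(adj[a]) - 1, len(adj[b]) - 1]
        ys += [len(adj[b]) - 1, len(adj[a]) - 1]
    if not xs:
        return float("nan")
    x = np.array(xs, dtype=float)
    y = np.array(ys, dtype=float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


# ---- communities -----------------------------------------------------------


def oracle_modularity(graph, membership: dict, weight_attr=None) -> float:
    """Q accumulated community-by-community from totals, the dual of the
    package's edge-by-edge route."""
    comms = set(membership.values())
    m = 0.0
    internal = {c: 0.0 for c in comms}
    degree_sum = {c: 0.0 for c in comms}
    for a, b, data in graph.edges(data=True):
        w = 1.0 if weight_attr is None else float(data[weight_attr])
        m += w
        if membership[a] == membership[b]:
            internal[membership[a]] += w
        degree_sum[membership[a]] += w
        degree_sum[membership[b]] += w
    if m == 0:
        return 0.0
    return sum(
        internal[c] / m - (degree_sum[c] / (2 * m)) ** 2 for c in comms
    )


def set_partitions(items: list):
    """All partitions of a small item list (Bell-number many)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def best_partition_exhaustive(graph) -> tuple[float, list]:
    """Globally optimal modularity over every partition (tiny graphs only)."""
    nodes = list(graph.nodes)
    best_q, best = -1.0, None
    for part in set_partitions(nodes):
        membership = {n: i for i, block in enumerate(part) for n in block}
        q = oracle_modularity(graph, membership)
        if q > best_q:
            best_q, best = q, part
    return best_q, best


# ---- interaction detection -------------------------------------------------


def oracle_detect_events(traj, criteria) -> list[tuple]:
    """Frame-scan interaction detection: walk every frame of every pair,
    maintaining the current run explicitly.  Returns (fly_a, fly_b, start,
    end) tuples sorted like the package output."""
    pos, roster = traj.position_array()
    fps = traj.arena.fps
    min_frames = int(np.ceil(criteria.min_duration_s * fps))
    body = traj.body_length_by_fly()
    events = []
    for ia in range(len(roster)):
        for ib in range(ia + 1, len(roster)):
            if body is not None:
                thr = criteria.distance_threshold_bl * (
                    (body[roster[ia]] + body[roster[ib]]) / 2.0
                )
            else:
                thr = criteria.distance_threshold_bl * criteria.body_length_mm
            runs = []
            start = None
            for f in range(traj.n_frames):
                xa, ya = pos[f, ia]
                xb, yb = pos[f, ib]
                ok = (
                    np.isfinite(xa)
                    and np.isfinite(xb)
                    and np.isfinite(ya)
                    and np.isfinite(yb)
                    and np.hypot(xa - xb, ya - yb) <= thr
                )
                if ok and start is None:
                    start = f
                elif not ok and start is not None:
                    runs.append((start, f))
                    start = None
            if start is not None:
                runs.append((start, traj.n_frames))
            # gap fusion, refusing to bridge frames where either fly is missing
            fused = []
            for s, e in runs:
                if (
                    fused
                    and s - fused[-1][1] <= criteria.gap_tolerance_frames
                    and all(
                        np.isfinite(pos[f, ia]).all()
                        and np.isfinite(pos[f, ib]).all()
                        for f in range(fused[-1][1], s)
                    )
                ):
                    fused[-1] = (fused[-1][0], e)
                else:
                    fused.append((s, e))
            for s, e in fused:
                if e - s >= min_frames:
                    events.append((roster[ia], roster[ib], s, e))
    events.sort(key=lambda e: (str(e[0]), str(e[1]), e[2]))
    return events
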