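"""Per-fly (local) network measures.

Degree centrality, node strength (count- and duration-weighted), closeness,
betweenness, eigenvector and information (current-flow closeness)
centrality, and the local clustering coefficient, each normalised as in the
standard network-science definitions.  Distance-based and spectral measures
(closeness, betweenness, eigenvector, information) are computed on the
largest connected component — the convention for fragmented social networks
— and flies outside it score 0, so every table stays total over the roster.
Weighted path measures convert a tie weight w into a length 1/w: a heavier
tie is a closer social relationship.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from flysin.errors import DegenerateInputError, ParameterError

#: column order of the local measure table
MEASURE_COLUMNS = [
    "dc",
    "s_count",
    "s_duration",
    "cc",
    "bc",
    "ec",
    "ic",
    "C",
    "C_wcount",
    "C_wduration",
]

_WEIGHT_ATTR = {"none": None, "count": "w_count", "duration": "w_duration"}


def _weight_attr(weight: str) -> str | None:
    try:
        return _WEIGHT_ATTR[weight]
    except KeyError:
        raise ParameterError(
            f"unknown weight kind '{weight}'; expected none|count|duration"
        ) from None


def _largest_component(sin: nx.Graph) -> nx.Graph:
    """Largest connected component; size ties broken by smallest node id
    (string order) so the choice is reproducible."""
    if sin.number_of_nodes() == 0:
        return sin
    comps = sorted(
        nx.connected_components(sin),
        key=lambda c: (-len(c), min(str(n) for n in c)),
    )
    return sin.subgraph(comps[0])


def _with_inverse_lengths(g: nx.Graph, attr: str) -> nx.Graph:
    h = nx.Graph()
    h.add_nodes_from(g.nodes)
    for a, b, d in g.edges(data=True):
        h.add_edge(a, b, _len=1.0 / d[attr])
    return h


def degree_centrality(sin: nx.Graph) -> dict:
    """k_i / (N - 1) for every fly."""
    if sin.number_of_nodes() < 2:
        raise DegenerateInputError("degree centrality needs at least 2 nodes")
    return nx.degree_centrality(sin)


def node_strength(sin: nx.Graph, weight: str = "duration") -> dict:
    """Sum of incident edge weights (count or duration) per fly."""
    attr = _weight_attr(weight)
    if attr is None:
        raise ParameterError("node strength requires weight 'count' or 'duration'")
    return {n: float(s) for n, s in sin.degree(weight=attr)}


def closeness_centrality(sin: nx.Graph, weight: str = "none") -> dict:
    """Normalised closeness on the largest component; 0 outside it."""
    attr = _weight_attr(weight)
    comp = _largest_component(sin)
    if attr is None:
        vals = nx.closeness_centrality(comp)
    else:
        vals = nx.closeness_centrality(
            _with_inverse_lengths(comp, attr), distance="_len"
        )
    return {n: vals.get(n, 0.0) for n in sin.nodes}


def betweenness_centrality(sin: nx.Graph, weight: str = "none") -> dict:
    """Shortest-path betweenness normalised by (N-1)(N-2) pairs of the
    largest component; 0 outside it."""
    attr = _weight_attr(weight)
    comp = _largest_component(sin)
    if attr is None:
        vals = nx.betweenness_centrality(comp, normalized=True)
    else:
        vals = nx.betweenness_centrality(
            _with_inverse_lengths(comp, attr), normalized=True, weight="_len"
        )
    return {n: vals.get(n, 0.0) for n in sin.nodes}


def eigenvector_centrality(
    sin: nx.Graph, max_iter: int = 1000, tol: float = 1e-10
) -> dict:
    """Principal adjacency eigenvector of the largest component, entries
    non-negative with unit Euclidean norm; 0 outside the component."""
    comp = _largest_component(sin)
    if comp.number_of_nodes() < 2:
        raise DegenerateInputError(
            "eigenvector centrality needs a component of >= 2 nodes"
        )
    try:
        vals = nx.eigenvector_centrality(comp, max_iter=max_iter, tol=tol)
    except nx.PowerIterationFailedConvergence as exc:
        raise ArithmeticError(
            f"power iteration failed to converge in {max_iter} iterations"
        ) from exc
    norm = np.sqrt(sum(v * v for v in vals.values()))
    return {n: vals.get(n, 0.0) / norm if n in vals else 0.0 for n in sin.nodes}


def information_centrality(sin: nx.Graph) -> dict:
    """Current-flow closeness (information) centrality on the largest
    component, from effective resistances of the component Laplacian;
    0 outside it."""
    comp = _largest_component(sin)
    if comp.number_of_nodes() < 2:
        raise DegenerateInputError(
            "information centrality needs a component of >= 2 nodes"
        )
    vals = nx.information_centrality(comp)
    return {n: vals.get(n, 0.0) for n in sin.nodes}


def local_clustering(sin: nx.Graph, weight: str = "none") -> dict:
    """Fraction of realised links among a fly's neighbours; flies with
    fewer than two neighbours score 0.  Weighted variants use the
    geometric-mean triangle intensity."""
    attr = _weight_attr(weight)
    return nx.clustering(sin, weight=attr)


def local_measure_table(sin: nx.Graph) -> pd.DataFrame:
    """All local measures, one row per roster fly.

    Columns: ``dc, s_count, s_duration, cc, bc, ec, ic, C, C_wcount,
    C_wduration``.  Per-network medians/means are available via
    ``df.median()`` / ``df.mean()``; isolated-only networks yield the
    all-zero table.
    """
    nodes = list(sin.nodes)
    n = len(nodes)
    if n == 0:
        return pd.DataFrame(columns=MEASURE_COLUMNS)
    zero = {v: 0.0 for v in nodes}

    dc = degree_centrality(sin) if n >= 2 else dict(zero)
    comp_size = len(max(nx.connected_components(sin), key=len)) if n else 0
    if comp_size >= 2:
        ec = eigenvector_centrality(sin)
        ic = information_centrality(sin)
    else:
        ec, ic = dict(zero), dict(zero)
    cols = {
        "dc": dc,
        "s_count": node_strength(sin, "count"),
        "s_duration": node_strength(sin, "duration"),
        "cc": closeness_centrality(sin),
        "bc": betweenness_centrality(sin),
        "ec": ec,
        "ic": ic,
        "C": local_clustering(sin),
        "C_wcount": local_clustering(sin, "count"),
        "C_wduration": local_clustering(sin, "duration"),
    }
    df = pd.DataFrame({k: [v[node] for node in nodes] for k, v in cols.items()})
    df.index = pd.Index(nodes, name="fly_id")
    return df[MEASURE_COLUMNS]
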