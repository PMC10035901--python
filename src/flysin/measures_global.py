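"""Whole-network (global) measures and the one-row summary table.

Distance measures (average shortest path L, diameter D, global efficiency)
are computed on the largest connected component only, the usual convention
for fragmented social networks.  Measures that are mathematically undefined
for a given graph — the diameter of an edgeless network, the assortativity
of a regular one — are reported as NaN, never as a silent zero, so that
population aggregation can distinguish "zero" from "no value".
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields

import numpy as np
import networkx as nx

from flysin.measures_local import _largest_component, local_clustering, node_strength

#: printed-report precision (two decimals, as in summary tables)
REPORT_DECIMALS = 2


@dataclass
class GlobalSummary:
    """One network's global measures; NaN marks undefined entries."""

    n_nodes: int
    n_links: int
    avg_degree: float
    avg_strength_count: float
    avg_strength_duration: float
    avg_links_per_node: float
    density: float
    avg_shortest_path: float
    diameter: float
    global_efficiency: float
    avg_clustering: float
    transitivity: float
    heterogeneity: float
    assortativity: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def rounded(self) -> dict:
        """Report form: floats rounded to two decimals."""
        out = {}
        for k, v in self.as_dict().items():
            out[k] = round(v, REPORT_DECIMALS) if isinstance(v, float) else v
        return out


def avg_shortest_path(sin: nx.Graph) -> float:
    """Mean shortest-path length over ordered pairs of the largest
    component; NaN when that component is a single fly."""
    comp = _largest_component(sin)
    if comp.number_of_nodes() < 2:
        return math.nan
    return nx.average_shortest_path_length(comp)


def diameter(sin: nx.Graph) -> float:
    """Longest shortest path on the largest component; NaN if degenerate."""
    comp = _largest_component(sin)
    if comp.number_of_nodes() < 2:
        return math.nan
    return float(nx.diameter(comp))


def global_efficiency(sin: nx.Graph) -> float:
    """Mean inverse shortest-path length over ordered pairs of the largest
    component."""
    comp = _largest_component(sin)
    if comp.number_of_nodes() < 2:
        return math.nan
    return nx.global_efficiency(nx.Graph(comp))


def avg_clustering(sin: nx.Graph, weight: str = "none") -> float:
    """Mean local clustering coefficient over all flies."""
    if sin.number_of_nodes() == 0:
        return math.nan
    vals = local_clustering(sin, weight)
    return float(np.mean(list(vals.values())))


def transitivity(sin: nx.Graph) -> float:
    """3 x triangles / triads; 0 by convention when the graph has no triads."""
    return nx.transitivity(sin)


def density(sin: nx.Graph) -> float:
    """2K / (N(N-1)); NaN for fewer than two flies."""
    n = sin.number_of_nodes()
    if n < 2:
        return math.nan
    return nx.density(sin)


def degree_heterogeneity(sin: nx.Graph) -> float:
    """Population standard deviation of degrees over the mean degree;
    NaN when the mean degree is 0."""
    degrees = np.array([d for _, d in sin.degree()], dtype=float)
    if degrees.size == 0 or degrees.mean() == 0:
        return math.nan
    return float(degrees.std() / degrees.mean())


def assortativity(sin: nx.Graph) -> float:
    """Degree assortativity: Pearson correlation of excess degrees over
    edge endpoints (both orientations); NaN when degenerate (no edges, or
    zero excess-degree variance as in regular graphs)."""
    if sin.number_of_edges() == 0:
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            r = nx.degree_assortativity_coefficient(sin)
        except (ZeroDivisionError, ValueError):
            return math.nan
    return float(r) if np.isfinite(r) else math.nan


def global_summary(sin: nx.Graph) -> GlobalSummary:
    """Assemble every global measure for one network."""
    n = sin.number_of_nodes()
    k = sin.number_of_edges()
    s_count = node_strength(sin, "count")
    s_dur = node_strength(sin, "duration")
    return GlobalSummary(
        n_nodes=n,
        n_links=k,
        avg_degree=2 * k / n if n else math.nan,
        avg_strength_count=float(np.mean(list(s_count.values()))) if n else math.nan,
        avg_strength_duration=float(np.mean(list(s_dur.values()))) if n else math.nan,
        avg_links_per_node=k / n if n else math.nan,
        density=density(sin),
        avg_shortest_path=avg_shortest_path(sin),
        diameter=diameter(sin),
        global_efficiency=global_efficiency(sin),
        avg_clustering=avg_clustering(sin),
        transitivity=transitivity(sin),
        heterogeneity=degree_heterogeneity(sin),
        assortativity=assortativity(sin),
    )
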