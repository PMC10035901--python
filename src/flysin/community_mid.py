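"""Middle-level (community) analysis: Louvain partitioning, modularity and
community summary statistics.

Communities are found with the Louvain algorithm — greedy modularity
optimisation by local node moves followed by graph aggregation — seeded for
reproducibility because the result is order-dependent.  The duration weight
is the analysis default: how long two flies spend together is the stronger
signal of a social tie than how often they brush past each other.
Modularity Q = sum_i (e_ii - a_i^2), where e_ii is the fraction of total
edge weight internal to community i and a_i the fraction of edge ends
attached to it; Q lies in [-0.5, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from collections import Counter

import networkx as nx

from flysin.errors import ParameterError
from flysin.measures_local import _weight_attr


@dataclass(frozen=True)
class Partition:
    """Assignment of every fly to exactly one community."""

    membership: dict
    weight_used: str = "duration"
    seed: int = 0
    resolution: float = 1.0

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def communities(self) -> list[set]:
        """Communities as node sets, largest first."""
        groups: dict = {}
        for node, com in self.membership.items():
            groups.setdefault(com, set()).add(node)
        return sorted(groups.values(), key=len, reverse=True)


@dataclass(frozen=True)
class CommunityStats:
    """Community- and component-level descriptors of one network."""

    n_nodes: int
    n_communities: int
    n_single_element: int
    pct_single_element: float
    n_communities_without_single: int
    biggest_size: int
    second_biggest_size: int
    avg_size_without_single: float
    n_components: int
    biggest_component_size: int
    modularity: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def louvain_partition(
    sin: nx.Graph,
    weight: str = "duration",
    seed: int = 0,
    resolution: float = 1.0,
) -> Partition:
    """Louvain community detection, deterministic for a given seed.

    Isolated flies always end up as singleton communities (no merge across
    components can raise modularity).
    """
    if resolution <= 0:
        raise ParameterError("resolution must be > 0")
    attr = _weight_attr(weight)
    comms = nx.community.louvain_communities(
        sin, weight=attr, seed=seed, resolution=resolution
    )
    membership = {}
    for label, com in enumerate(comms):
        for node in com:
            membership[node] = label
    return Partition(
        membership=membership, weight_used=weight, seed=seed, resolution=resolution
    )


def modularity(sin: nx.Graph, partition: Partition, weight: str = "duration") -> float:
    """Modularity Q of a partition, accumulated edge by edge.

    For each community i, e_ii is the fraction of total (weighted) links
    internal to i and a_i the fraction of link ends attached to i;
    Q = sum_i (e_ii - a_i^2).  Unweighted when ``weight`` is ``none``.
    An edgeless network has no links to apportion: Q = 0.
    """
    attr = _weight_attr(weight)
    missing = [n for n in sin.nodes if n not in partition.membership]
    if missing:
        raise ParameterError(f"partition does not cover nodes: {missing[:5]}")
    two_m = 0.0
    internal: Counter = Counter()  # e_ii numerators (full weight per edge)
    ends: Counter = Counter()  # a_i numerators (edge ends)
    for a, b, d in sin.edges(data=True):
        w = 1.0 if attr is None else float(d[attr])
        two_m += 2 * w
        ca, cb = partition.membership[a], partition.membership[b]
        if ca == cb:
            internal[ca] += w
        ends[ca] += w
        ends[cb] += w
    if two_m == 0:
        return 0.0
    m = two_m / 2.0
    return sum(
        internal[c] / m - (ends[c] / two_m) ** 2
        for c in set(partition.membership.values())
    )


def connected_components(sin: nx.Graph) -> tuple[int, list[int]]:
    """Number of connected components and their sizes, largest first."""
    sizes = sorted((len(c) for c in nx.connected_components(sin)), reverse=True)
    return len(sizes), sizes


def community_stats(
    sin: nx.Graph, partition: Partition, weight: str = "duration"
) -> CommunityStats:
    """Summary-row statistics for one partitioned network.

    Singleton communities are counted in the community ranking;
    ``pct_single_element`` uses the community count as denominator.
    """
    sizes = sorted((len(c) for c in partition.communities()), reverse=True)
    n_single = sum(1 for s in sizes if s == 1)
    multi = [s for s in sizes if s > 1]
    n_comp, comp_sizes = connected_components(sin)
    return CommunityStats(
        n_nodes=sin.number_of_nodes(),
        n_communities=len(sizes),
        n_single_element=n_single,
        pct_single_element=100.0 * n_single / len(sizes) if sizes else 0.0,
        n_communities_without_single=len(multi),
        biggest_size=sizes[0] if sizes else 0,
        second_biggest_size=sizes[1] if len(sizes) > 1 else 0,
        avg_size_without_single=sum(multi) / len(multi) if multi else 0.0,
        n_components=n_comp,
        biggest_component_size=comp_sizes[0] if comp_sizes else 0,
        modularity=modularity(sin, partition, weight),
    )
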