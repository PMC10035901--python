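"""Construction and serialization of social interaction networks (SINs).

A SIN is an undirected weighted ``networkx.Graph``: nodes are individual
flies (the full roster, so flies that never interacted appear as isolated
nodes) and each interacting pair carries exactly one edge with two weights
— ``w_count``, the number of interaction events, and ``w_duration``, their
summed duration in seconds.  Graph-level attributes (``label``,
``condition`` and optionally the detection parameters) make exported files
self-describing for downstream measure tables and Gephi visualisation.
"""

from __future__ import annotations

import csv

import networkx as nx

from flysin.errors import FormatError, IdentifierError, ParameterError
from flysin.interaction_detect import InteractionEvent, events_summary

GRAPH_FORMATS = ("graphml", "gexf", "edgelist-csv")


def build_sin(
    events: list[InteractionEvent],
    roster,
    label: str = "",
    condition: str = "",
    **graph_attrs,
) -> nx.Graph:
    """Build the SIN for one group of flies.

    ``roster`` fixes the node set regardless of who interacted; an event
    naming a fly outside the roster is an error.  Extra keyword arguments
    become graph-level attributes (e.g. fps or thresholds used).
    """
    roster = list(roster)
    known = set(roster)
    for e in events:
        for fly in (e.fly_a, e.fly_b):
            if fly not in known:
                raise IdentifierError(f"event references fly '{fly}' not in roster")
    g = nx.Graph(label=label, condition=condition, **graph_attrs)
    g.add_nodes_from(roster)
    per_pair, _ = events_summary(events)
    for row in per_pair.itertuples():
        g.add_edge(
            row.fly_a,
            row.fly_b,
            w_count=int(row.n_events),
            w_duration=float(row.total_duration_s),
        )
    return g


def export_graph(sin: nx.Graph, path, format: str = "graphml") -> None:
    """Write a SIN to ``graphml``, ``gexf`` or ``edgelist-csv``."""
    if format == "graphml":
        nx.write_graphml(sin, path)
    elif format == "gexf":
        nx.write_gexf(sin, path)
    elif format == "edgelist-csv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["fly_a", "fly_b", "w_count", "w_duration"])
            for a, b, d in sin.edges(data=True):
                w.writerow([a, b, d["w_count"], d["w_duration"]])
    else:
        raise ParameterError(
            f"unknown graph format '{format}'; expected one of {GRAPH_FORMATS}"
        )


def import_graph(path, format: str = "graphml") -> nx.Graph:
    """Read a SIN written by :func:`export_graph`; both weights required."""
    if format == "graphml":
        g = nx.read_graphml(path)
    elif format == "gexf":
        g = nx.read_gexf(path)
    elif format == "edgelist-csv":
        g = nx.Graph()
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {
                "fly_a",
                "fly_b",
                "w_count",
                "w_duration",
            } <= set(reader.fieldnames):
                raise FormatError(f"{path}: edge list must have fly_a,fly_b,w_count,w_duration")
            for row in reader:
                g.add_edge(
                    row["fly_a"],
                    row["fly_b"],
                    w_count=int(row["w_count"]),
                    w_duration=float(row["w_duration"]),
                )
        return g
    else:
        raise ParameterError(
            f"unknown graph format '{format}'; expected one of {GRAPH_FORMATS}"
        )
    for a, b, d in g.edges(data=True):
        for attr in ("w_count", "w_duration"):
            if attr not in d:
                raise FormatError(f"{path}: edge ({a},{b}) missing weight '{attr}'")
        d["w_count"] = int(d["w_count"])
        d["w_duration"] = float(d["w_duration"])
    return g


def total_weights(sin: nx.Graph) -> dict:
    """Sums of both edge weights over the network (conservation checks)."""
    return {
        "w_count": sum(d["w_count"] for _, _, d in sin.edges(data=True)),
        "w_duration": sum(d["w_duration"] for _, _, d in sin.edges(data=True)),
    }
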