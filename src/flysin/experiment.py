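"""End-to-end experiment drivers: simulate populations, build their SINs,
and summarise the measures used for population comparison.

These wrap the full pipeline (simulate -> detect -> build -> measure) so a
two-population experiment — e.g. 9 control-like vs 11 drug-like groups of
30 flies recorded for 10 minutes — is a single call, reproducible from one
base seed.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import pandas as pd

from flysin.community_mid import community_stats, louvain_partition
from flysin.interaction_detect import InteractionCriteria, detect_events
from flysin.measures_global import global_summary
from flysin.sin_model import build_sin
from flysin.synth import SimConfig, preset, simulate_arena

#: measures reported per network in experiment summaries
SUMMARY_MEASURES = [
    "density",
    "avg_strength_count",
    "avg_strength_duration",
    "avg_shortest_path",
    "modularity",
    "pct_single_element",
    "n_single_element",
]


def simulate_network(
    config: SimConfig,
    criteria: InteractionCriteria | None = None,
    label: str = "",
    condition: str = "",
) -> nx.Graph:
    """Simulate one group and return its social interaction network."""
    traj = simulate_arena(config)
    events = detect_events(traj, criteria)
    return build_sin(events, traj.roster, label=label, condition=condition)


def population_networks(
    base: SimConfig,
    n_groups: int,
    base_seed: int,
    condition: str = "",
    criteria: InteractionCriteria | None = None,
) -> list[nx.Graph]:
    """Simulate ``n_groups`` independent recordings (seeds base_seed + g)."""
    return [
        simulate_network(
            dataclasses.replace(base, seed=base_seed + g),
            criteria,
            label=f"{condition}_{g:02d}",
            condition=condition,
        )
        for g in range(n_groups)
    ]


def summarize_networks(
    sins: list[nx.Graph], community_seed: int = 0
) -> pd.DataFrame:
    """One row per network with the comparison measures: global density,
    mean strengths, average shortest path, and the duration-weighted
    Louvain community statistics."""
    rows = []
    for sin in sins:
        gs = global_summary(sin)
        part = louvain_partition(sin, weight="duration", seed=community_seed)
        cs = community_stats(sin, part, weight="duration")
        rows.append(
            {
                "label": sin.graph.get("label", ""),
                "density": gs.density,
                "avg_strength_count": gs.avg_strength_count,
                "avg_strength_duration": gs.avg_strength_duration,
                "avg_shortest_path": gs.avg_shortest_path,
                "modularity": cs.modularity,
                "pct_single_element": cs.pct_single_element,
                "n_single_element": cs.n_single_element,
            }
        )
    return pd.DataFrame(rows)


def two_population_experiment(
    base_seed: int,
    n_ctrl: int = 9,
    n_coc: int = 11,
    ctrl_config: SimConfig | None = None,
    coc_config: SimConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full two-population recording design and summarise it.

    Defaults reproduce the study design: 9 control-like and 11 drug-like
    groups of 30 flies, 10 minutes at 24 fps.  Returns (ctrl_summary,
    coc_summary), one row per group.  Seeds are ``base_seed + g`` for the
    control groups and ``base_seed + 1000 + g`` for the drug groups.
    """
    ctrl = ctrl_config if ctrl_config is not None else preset("ctrl_like")
    coc = coc_config if coc_config is not None else preset("coc_like")
    nets_ctrl = population_networks(ctrl, n_ctrl, base_seed, "CTRL")
    nets_coc = population_networks(coc, n_coc, base_seed + 1000, "COC")
    return summarize_networks(nets_ctrl), summarize_networks(nets_coc)
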