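import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flysin.errors import DegenerateInputError, ParameterError
from flysin.measures_local import (
    MEASURE_COLUMNS,
    betweenness_centrality,
    closeness_centrality,
    degree_centrality,
    eigenvector_centrality,
    information_centrality,
    local_clustering,
    local_measure_table,
    node_strength,
)
from flysin.synth import graph_fixture

import oracles


def weighted_sin(edges):
    g = nx.Graph()
    for a, b, c, d in edges:
        g.add_edge(a, b, w_count=c, w_duration=d)
    return g


class TestClosedForms:
    def test_star_degree_centrality(self):
        dc = degree_centrality(graph_fixture("star5"))
        assert dc[0] == pytest.approx(1.0)
        assert all(dc[i] == pytest.approx(0.25) for i in range(1, 5))

    def test_path_closeness(self):
        cc = closeness_centrality(graph_fixture("path3"))
        assert cc[1] == pytest.approx(1.0)
        assert cc[0] == pytest.approx(2 / 3)
        assert cc[2] == pytest.approx(2 / 3)

    def test_path_betweenness(self):
        bc = betweenness_centrality(graph_fixture("path3"))
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_complete_graph_betweenness_zero(self):
        assert all(
            v == 0.0 for v in betweenness_centrality(graph_fixture("k5")).values()
        )

    def test_k3_eigenvector_symmetric(self):
        ec = eigenvector_centrality(graph_fixture("k3"))
        for v in ec.values():
            assert v == pytest.approx(1 / math.sqrt(3), abs=1e-8)

    def test_star_eigenvector_ordering(self):
        ec = eigenvector_centrality(graph_fixture("star5"))
        leaves = [ec[i] for i in range(1, 5)]
        assert ec[0] > max(leaves)
        assert max(leaves) == pytest.approx(min(leaves), abs=1e-9)

    def test_k3_information_symmetric(self):
        ic = information_centrality(graph_fixture("k3"))
        vals = list(ic.values())
        assert vals[0] == pytest.approx(vals[1]) == pytest.approx(vals[2])

    def test_star_information_hub_dominates(self):
        sin = graph_fixture("star5")
        ic = information_centrality(sin)
        expected = oracles.oracle_information_centrality(sin)
        for n in sin.nodes:
            assert ic[n] == pytest.approx(expected[n], abs=1e-9)
        assert ic[0] > ic[1]

    def test_clustering_closed_forms(self):
        assert local_clustering(graph_fixture("k3"))[0] == pytest.approx(1.0)
        assert local_clustering(graph_fixture("path3"))[1] == 0.0
        assert local_clustering(graph_fixture("star5"))[0] == 0.0

    def test_strengths(self):
        sin = weighted_sin([("a", "b", 2, 1.5), ("a", "c", 1, 2.5)])
        assert node_strength(sin, "duration")["a"] == pytest.approx(4.0)
        assert node_strength(sin, "count")["a"] == pytest.approx(3)
        sin.add_node("d")
        assert node_strength(sin, "count")["d"] == 0


class TestConventions:
    def test_isolated_nodes_score_zero(self):
        sin = graph_fixture("k3")
        sin.add_node(99)
        assert closeness_centrality(sin)[99] == 0.0
        assert eigenvector_centrality(sin)[99] == 0.0
        assert information_centrality(sin)[99] == 0.0
        assert closeness_centrality(sin)[0] == pytest.approx(1.0)

    def test_degenerate_inputs(self):
        single = nx.Graph()
        single.add_node("a")
        with pytest.raises(DegenerateInputError):
            degree_centrality(single)
        isolated = nx.Graph()
        isolated.add_nodes_from("abc")
        with pytest.raises(DegenerateInputError):
            eigenvector_centrality(isolated)

    def test_unknown_weight_kind(self):
        with pytest.raises(ParameterError):
            node_strength(graph_fixture("k3"), "frames")
        with pytest.raises(ParameterError):
            local_clustering(graph_fixture("k3"), "frames")

    def test_weighted_betweenness_prefers_heavy_ties(self):
        """With length 1/w, a heavy two-hop route beats a light direct edge."""
        sin = weighted_sin(
            [("a", "b", 1, 1.0), ("a", "m", 1, 10.0), ("m", "b", 1, 10.0)]
        )
        bc = betweenness_centrality(sin, weight="duration")
        assert bc["m"] == pytest.approx(1.0)


class TestOracleEquivalence:
    @pytest.mark.parametrize("name", ["path3", "star5", "k3", "k5",
                                      "two_triangles", "k5_plus_isolates"])
    def test_fixtures(self, name):
        sin = graph_fixture(name)
        self._check(sin)

    @pytest.mark.parametrize("seed", range(30))
    def test_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        p = float(rng.uniform(0.1, 0.9))
        self._check(graph_fixture("random", n=n, p=p, seed=seed))

    def _check(self, sin):
        if sin.number_of_nodes() >= 2:
            for node, v in degree_centrality(sin).items():
                assert v == pytest.approx(
                    oracles.oracle_degree_centrality(sin)[node], abs=1e-9
                )
        for ours, theirs in [
            (closeness_centrality(sin), oracles.oracle_closeness(sin)),
            (betweenness_centrality(sin), oracles.oracle_betweenness(sin)),
            (local_clustering(sin), oracles.oracle_local_clustering(sin)),
        ]:
            for node in sin.nodes:
                assert ours[node] == pytest.approx(theirs[node], abs=1e-9)
        comp = max((len(c) for c in nx.connected_components(sin)), default=0)
        if comp >= 2:
            ic = information_centrality(sin)
            ic_oracle = oracles.oracle_information_centrality(sin)
            for node in sin.nodes:
                assert ic[node] == pytest.approx(ic_oracle[node], abs=1e-9)
            ec = eigenvector_centrality(sin)
            ec_oracle = oracles.oracle_eigenvector(sin)
            for node in sin.nodes:
                assert ec[node] == pytest.approx(ec_oracle[node], abs=1e-6)


class TestProperties:
    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_relabeling_equivariance(self, seed):
        sin = graph_fixture("random", n=7, p=0.4, seed=seed)
        mapping = {i: f"fly{(i * 3) % 7}" for i in range(7)}
        relabeled = nx.relabel_nodes(sin, mapping)
        bc = betweenness_centrality(sin)
        bc2 = betweenness_centrality(relabeled)
        cc = closeness_centrality(sin)
        cc2 = closeness_centrality(relabeled)
        for i in range(7):
            assert bc2[mapping[i]] == pytest.approx(bc[i], abs=1e-12)
            assert cc2[mapping[i]] == pytest.approx(cc[i], abs=1e-12)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_adding_edge_never_decreases_degree_centrality(self, seed):
        rng = np.random.default_rng(seed)
        sin = graph_fixture("random", n=8, p=0.3, seed=seed)
        non_edges = list(nx.non_edges(sin))
        if not non_edges:
            return
        a, b = non_edges[rng.integers(len(non_edges))]
        before = degree_centrality(sin)
        sin.add_edge(a, b, w_count=1, w_duration=1.0)
        after = degree_centrality(sin)
        assert all(after[n] >= before[n] - 1e-12 for n in sin.nodes)

    @pytest.mark.parametrize("name", ["k3", "k5"])
    def test_vertex_transitive_constant(self, name):
        """Cycles and complete graphs: every measure constant over nodes."""
        sin = graph_fixture(name)
        table = local_measure_table(sin)
        for col in MEASURE_COLUMNS:
            assert table[col].nunique() == 1

    def test_cycle_constant(self):
        g = nx.cycle_graph(6)
        sin = nx.Graph()
        sin.add_nodes_from(g.nodes)
        for a, b in g.edges:
            sin.add_edge(a, b, w_count=1, w_duration=1.0)
        table = local_measure_table(sin)
        for col in MEASURE_COLUMNS:
            assert table[col].round(9).nunique() == 1


class TestMeasureTable:
    def test_all_isolated_is_all_zero(self):
        sin = nx.Graph()
        sin.add_nodes_from(range(30))
        table = local_measure_table(sin)
        assert len(table) == 30
        assert (table.to_numpy() == 0).all()

    def test_k3_row(self):
        table = local_measure_table(graph_fixture("k3"))
        assert (table["dc"] == 1.0).all()
        assert (table["cc"] == 1.0).all()
        assert (table["C"] == 1.0).all()

    def test_row_count_is_roster_size(self, rng):
        sin = graph_fixture("k5_plus_isolates")
        assert len(local_measure_table(sin)) == 10
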