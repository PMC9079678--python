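"""Communities, shortest regulation pathways, perturbation, and the
transfer-efficiency statistic."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynet.analysis import (
    average_spl,
    efficiency_report,
    count_isolated,
    count_path_nodes,
    girvan_newman,
    parse_pathway,
    shortest_path,
    transfer_efficiency,
    weaken_ligand,
)
from dynet.corrnet import consensus_network
from dynet.datasets import m2_pathway_spls, m2_spl_table

from _util import (
    brute_force_shortest,
    graph_network,
    planted_block_graph,
    random_length_graph,
)


def _weighted(edges):
    g = nx.Graph()
    for u, v, w in edges:
        g.add_edge(u, v, weight=w, length=float(-math.log(w)))
    return g


class TestGirvanNewman:
    def test_two_triangles_with_bridge(self):
        g = _weighted([
            (0, 1, 0.8), (1, 2, 0.8), (0, 2, 0.8),
            (3, 4, 0.8), (4, 5, 0.8), (3, 5, 0.8),
            (2, 3, 0.3),
        ])
        part = girvan_newman(graph_network(g))
        assert part.n_communities == 2
        assert part.membership[0] == part.membership[1] == part.membership[2]
        assert part.membership[3] == part.membership[4] == part.membership[5]

    def test_disconnected_triangles(self):
        g = _weighted([
            (0, 1, 0.8), (1, 2, 0.8), (0, 2, 0.8),
            (3, 4, 0.8), (4, 5, 0.8), (3, 5, 0.8),
        ])
        part = girvan_newman(graph_network(g))
        assert part.n_communities == 2
        assert part.n_isolated == 1

    def test_at_least_component_count(self):
        rng = np.random.default_rng(0)
        g = random_length_graph(rng, n_max=8)
        g.add_nodes_from(range(g.number_of_nodes(), g.number_of_nodes() + 3))
        part = girvan_newman(graph_network(g))
        assert part.n_communities >= nx.number_connected_components(g)

    def test_modularity_no_worse_than_single_community(self):
        for seed in range(5):
            g = random_length_graph(np.random.default_rng(seed), n_max=10)
            if g.number_of_edges() == 0:
                continue
            part = girvan_newman(graph_network(g))
            trivial = nx.community.modularity(
                g, [set(g.nodes)], weight="weight"
            )
            assert part.modularity >= trivial - 1e-12

    def test_deterministic_partition(self):
        g = _weighted([(0, 1, 0.5), (1, 2, 0.5), (2, 3, 0.5), (3, 0, 0.5)])
        a = girvan_newman(graph_network(g.copy()))
        b = girvan_newman(graph_network(g.copy()))
        assert a.membership == b.membership

    def test_planted_blocks_recovered(self, small_networks, small_system):
        from sklearn.metrics import adjusted_rand_score

        spec, _, _ = small_system
        cons = consensus_network(small_networks)
        part = girvan_newman(cons)
        truth = [spec.block_of[i] for i in range(spec.n_nodes)]
        found = [part.membership[i] for i in range(spec.n_nodes)]
        assert adjusted_rand_score(truth, found) >= 0.9

    def test_meta_network_aggregates_bridge_weights(self):
        g = _weighted([
            (0, 1, 0.8), (1, 2, 0.8), (0, 2, 0.8),
            (3, 4, 0.8), (4, 5, 0.8), (3, 5, 0.8),
            (2, 3, 0.3), (0, 5, 0.2),
        ])
        part = girvan_newman(graph_network(g))
        if part.n_communities == 2:
            assert part.meta_network[0][1]["weight"] == pytest.approx(0.5)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError):
            girvan_newman(graph_network(nx.Graph()))


class TestCountIsolated:
    def test_connected_network_has_none(self):
        g = _weighted([(0, 1, 0.5), (1, 2, 0.5)])
        part = girvan_newman(graph_network(g))
        assert count_isolated(part, graph_network(g)) == 0

    def test_two_detached_dimers(self):
        g = _weighted([
            (0, 1, 0.8), (1, 2, 0.8), (0, 2, 0.8), (2, 3, 0.8),
            (4, 5, 0.5),
            (6, 7, 0.5),
        ])
        net = graph_network(g)
        part = girvan_newman(net)
        assert count_isolated(part, net) == 2

    def test_detached_synthetic_blocks(self):
        from dynet.corrnet import build_network, contact_occupancy, correlation_matrix
        from dynet.synth import PlantedSpec, build_geometry, sample_trajectory

        k = 3  # blocks detached from the largest one
        spec = PlantedSpec(
            n_nodes=32, blocks=[[*range(8)], [*range(8, 16)], [*range(16, 24)], [*range(24, 32)]],
            pathway=[], extra_contacts=[], n_frames=800, n_replicates=1, seed=3,
        )
        traj = sample_trajectory(spec, build_geometry(spec))[0]
        net = build_network(
            correlation_matrix(traj), contact_occupancy(traj), traj.node_map
        )
        part = girvan_newman(net)
        assert count_isolated(part, net) == k


class TestShortestPath:
    def test_direct_edge_beats_detour(self):
        g = nx.Graph()
        g.add_edge(0, 2, weight=0.5, length=1.0)
        g.add_edge(0, 1, weight=0.5, length=1.5)
        g.add_edge(1, 2, weight=0.5, length=1.5)
        path = shortest_path(graph_network(g), 0, [2])
        assert path.nodes == [0, 2]
        assert path.total_length == pytest.approx(1.0)

    def test_unreachable_sink_flagged(self):
        g = nx.Graph()
        g.add_nodes_from(range(4))
        g.add_edge(0, 1, weight=0.5, length=1.0)
        path = shortest_path(graph_network(g), 0, [3])
        assert not path.reachable
        assert math.isinf(path.total_length)

    def test_lexicographic_tie_break(self):
        # two equal-length routes 0-1-3 and 0-2-3: pick the smaller ids
        g = nx.Graph()
        for u, v in [(0, 1), (1, 3), (0, 2), (2, 3)]:
            g.add_edge(u, v, weight=0.5, length=1.0)
        path = shortest_path(graph_network(g), 0, [3])
        assert path.nodes == [0, 1, 3]

    def test_nearest_sink_member_wins(self):
        g = nx.Graph()
        g.add_edge(0, 1, weight=0.5, length=1.0)
        g.add_edge(1, 2, weight=0.5, length=1.0)
        path = shortest_path(graph_network(g), 0, [1, 2])
        assert path.nodes == [0, 1]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        g = random_length_graph(rng)
        nodes = sorted(g.nodes)
        s, t = nodes[0], nodes[-1]
        net = graph_network(g)
        mine = shortest_path(net, s, [t])
        oracle_len, oracle_path = brute_force_shortest(g, s, t)
        if oracle_path is None:
            assert not mine.reachable
        else:
            assert mine.total_length == pytest.approx(oracle_len, abs=1e-9)

    def test_deleting_path_edge_never_shortens(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            g = random_length_graph(rng)
            nodes = sorted(g.nodes)
            net = graph_network(g)
            path = shortest_path(net, nodes[0], [nodes[-1]])
            if not path.reachable:
                continue
            g2 = g.copy()
            g2.remove_edge(path.nodes[0], path.nodes[1])
            after = shortest_path(graph_network(g2), nodes[0], [nodes[-1]])
            assert after.total_length >= path.total_length - 1e-12


class TestAverageSpl:
    def test_identical_replicates_have_zero_sd(self):
        g = _weighted([(0, 1, 0.5), (1, 2, 0.5)])
        nets = [graph_network(g.copy()) for _ in range(3)]
        summ = average_spl(nets, 0, [2])
        assert summ.sd == 0.0
        assert summ.mean == pytest.approx(2 * -math.log(0.5))

    def test_single_replicate(self):
        g = _weighted([(0, 1, 0.4)])
        summ = average_spl([graph_network(g)], 0, [1])
        assert summ.mean == pytest.approx(-math.log(0.4))
        assert summ.sd == 0.0

    def test_consensus_path_is_planted_chain(self, small_networks, small_system):
        spec, geometry, _ = small_system
        cons = consensus_network(small_networks)
        source = geometry.node_map.nodes[spec.source].label
        sink = geometry.node_map.nodes[spec.sink].label
        summ = average_spl(small_networks, source, [sink], consensus=cons)
        assert summ.consensus_path.nodes == spec.pathway
        assert min(summ.lengths) <= summ.mean <= max(summ.lengths)

    def test_all_unreachable(self):
        g = nx.Graph()
        g.add_nodes_from(range(3))
        summ = average_spl([graph_network(g)], 0, [2])
        assert not summ.reachable


class TestPathwayParsing:
    def test_bound_m2_modulator_pathway_has_six_intermediates(self):
        row = m2_spl_table()
        text = row.loc[
            (row.system == "Bound M2") & row.pathway.str.startswith("2CU"), "pathway"
        ].iloc[0]
        assert count_path_nodes(parse_pathway(text)) == 6

    def test_bound_m2_agonist_pathway_has_four_intermediates(self):
        assert count_path_nodes(parse_pathway("IXO-V111-F396-L114-Y440-Nb9")) == 4

    def test_direct_edge_has_none(self):
        assert count_path_nodes(parse_pathway("LIG-SINK")) == 0

    def test_non_pathway_string_rejected(self):
        with pytest.raises(ValueError):
            parse_pathway("JUSTONENODE")


class TestWeakenLigand:
    def test_ligand_degree_drops_to_zero(self):
        g, ligand, _ = planted_block_graph(np.random.default_rng(1))
        net = graph_network(g)
        before_edges = net.n_edges
        ligand_degree = net.graph.degree(ligand)
        weak = weaken_ligand(net, [ligand])
        assert weak.graph.degree(ligand) == 0
        assert weak.n_edges == before_edges - ligand_degree
        assert weak.n_nodes == net.n_nodes

    def test_input_network_untouched(self):
        g, ligand, _ = planted_block_graph(np.random.default_rng(2))
        net = graph_network(g)
        before = net.n_edges
        weaken_ligand(net, [ligand])
        assert net.n_edges == before

    def test_bridging_ligand_splits_communities(self):
        # ligand edges are the only link between two cliques
        g = _weighted([
            (0, 1, 0.8), (1, 2, 0.8), (0, 2, 0.8),
            (3, 4, 0.8), (4, 5, 0.8), (3, 5, 0.8),
            (6, 0, 0.7), (6, 3, 0.7),  # node 6 = ligand bridge
        ])
        net = graph_network(g)
        before = girvan_newman(net).n_communities
        weak = weaken_ligand(net, [6])
        after = girvan_newman(weak).n_communities
        assert after > before


class TestTransferEfficiency:
    def test_f396a_worked_example(self):
        eff = transfer_efficiency(
            m2_pathway_spls("Bound M2"), m2_pathway_spls("F396A")
        )
        assert round(eff, 2) == 59.05

    def test_identity_is_exactly_100(self):
        assert transfer_efficiency([4.2, 3.6], [4.2, 3.6]) == 100.0

    def test_doubled_spls_halve_efficiency(self):
        assert transfer_efficiency([2.0, 3.0], [4.0, 6.0]) == pytest.approx(50.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            transfer_efficiency([1.0], [0.0])

    def test_infinite_spl_rejected(self):
        with pytest.raises(ValueError):
            transfer_efficiency([1.0], [math.inf])

    @given(
        st.lists(st.floats(0.1, 50.0), min_size=1, max_size=6),
        st.floats(1.01, 10.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scaling_property(self, spls, factor):
        # scaling every system SPL by f divides the efficiency by f
        base = transfer_efficiency(spls, spls)
        scaled = transfer_efficiency(spls, [x * factor for x in spls])
        assert scaled == pytest.approx(base / factor, rel=1e-9)


    def test_report_builder_scores_all_systems(self):
        report = efficiency_report(
            "wild-type",
            {"wild-type": [4.20, 3.60], "F396A": [5.63, 7.58]},
        )
        assert report.efficiency_pct["wild-type"] == 100.0
        assert round(report.efficiency_pct["F396A"], 2) == 59.05
        assert report.spl_sums["F396A"] == pytest.approx(13.21)
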