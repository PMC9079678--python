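"""Correlation matrices, contact occupancy, network assembly, and the
topology summary (cross-checked against an independent scipy oracle)."""

import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.csgraph as csgraph

from dynet.corrnet import (
    build_network,
    contact_occupancy,
    correlation_matrix,
    consensus_network,
    network_summary,
    weighted_degrees,
    CorrelationMatrix,
    OccupancyMatrix,
)

from _util import bead_node_map, bead_trajectory, graph_network, random_length_graph


class TestCorrelationMatrix:
    def test_diagonal_is_one(self):
        rng = np.random.default_rng(0)
        traj = bead_trajectory(rng.normal(size=(50, 6, 3)))
        C = correlation_matrix(traj).values
        assert np.allclose(np.diag(C), 1.0, atol=1e-9)
        assert np.allclose(C, C.T, atol=1e-12)
        assert np.abs(C).max() <= 1.0 + 1e-12

    def test_mirrored_node_fully_anticorrelated(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(200, 1, 3))
        frames = np.concatenate([x, -x], axis=1)  # node 1 mirrors node 0
        C = correlation_matrix(bead_trajectory(frames)).values
        assert C[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_zero_variance_node_guarded(self):
        rng = np.random.default_rng(2)
        frames = rng.normal(size=(100, 3, 3))
        frames[:, 2] = 0.0  # frozen node
        with pytest.warns(UserWarning, match="zero fluctuation"):
            C = correlation_matrix(bead_trajectory(frames)).values
        assert C[2, 2] == 1.0
        assert np.allclose(C[2, :2], 0.0)

    def test_invariant_under_global_rigid_motion(self, small_system):
        import scipy.spatial.transform as sst

        _, _, trajectories = small_system
        traj = trajectories[0]
        C0 = correlation_matrix(traj).values
        R = sst.Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = traj.with_coords(traj.coords @ R.T + np.array([5.0, -3.0, 12.0]))
        C1 = correlation_matrix(moved).values
        assert np.allclose(C0, C1, atol=1e-9)

    def test_planted_correlation_recovered(self):
        from dynet.synth import PlantedSpec, build_geometry, sample_trajectory

        spec = PlantedSpec(
            n_nodes=8, blocks=[[*range(8)]], rho_intra=0.8,
            pathway=[], extra_contacts=[], n_frames=25_000, n_replicates=1, seed=21,
        )
        traj = sample_trajectory(spec, build_geometry(spec))[0]
        C = correlation_matrix(traj).values
        off = C[~np.eye(8, dtype=bool)]
        assert np.abs(off - 0.8).max() <= 0.02


class TestContactOccupancy:
    def _two_bead_traj(self, distances):
        frames = np.zeros((len(distances), 2, 3))
        frames[:, 1, 0] = distances
        return bead_trajectory(frames)

    def test_fixed_within_cutoff(self):
        occ = contact_occupancy(self._two_bead_traj([4.0] * 10)).values
        assert occ[0, 1] == 1.0

    def test_fixed_beyond_cutoff(self):
        occ = contact_occupancy(self._two_bead_traj([5.0] * 10)).values
        assert occ[0, 1] == 0.0

    def test_alternating_frames_give_half(self):
        occ = contact_occupancy(self._two_bead_traj([4.0, 6.0] * 25)).values
        assert occ[0, 1] == pytest.approx(0.5)

    def test_minimum_over_heavy_atom_pairs(self):
        # centers 6 A apart but side beads bridge to 3 A
        nm = bead_node_map(
            2, atom_names=[["CA", "CB"], ["CA", "CB"]],
            elements=[["C", "C"], ["C", "C"]],
        )
        frames = np.zeros((4, 4, 3))
        frames[:, 1] = (1.5, 0, 0)   # node 0: CB toward node 1
        frames[:, 2] = (6.0, 0, 0)   # node 1 CA
        frames[:, 3] = (4.5, 0, 0)   # node 1: CB toward node 0
        occ = contact_occupancy(bead_trajectory(frames, nm)).values
        assert occ[0, 1] == 1.0

    def test_matches_brute_force_recount(self, small_system):
        spec, geometry, trajectories = small_system
        traj = trajectories[0].with_coords(trajectories[0].coords[:100])
        occ = contact_occupancy(traj).values
        heavy = [n.heavy_atoms for n in geometry.node_map.nodes]
        rng = np.random.default_rng(0)
        for _ in range(25):
            i, j = sorted(rng.choice(spec.n_nodes, size=2, replace=False))
            hits = 0
            for f in range(traj.n_frames):
                d = np.linalg.norm(
                    traj.coords[f, heavy[i]][:, None] - traj.coords[f, heavy[j]][None],
                    axis=-1,
                ).min()
                hits += d < 4.5
            assert occ[i, j] == pytest.approx(hits / traj.n_frames)


class TestBuildNetwork:
    def _inputs(self, n=4):
        C = np.full((n, n), 0.5)
        np.fill_diagonal(C, 1.0)
        O = np.ones((n, n))
        nm = bead_node_map(n)
        return CorrelationMatrix(C, 10), OccupancyMatrix(O, 4.5, 10), nm

    def test_low_occupancy_pair_has_no_edge(self):
        corr, occ, nm = self._inputs()
        occ.values[0, 2] = occ.values[2, 0] = 0.5
        net = build_network(corr, occ, nm, exclusions=set())
        assert not net.graph.has_edge(0, 2)

    def test_covalent_neighbours_excluded(self):
        corr, occ, nm = self._inputs()
        net = build_network(corr, occ, nm)  # default exclusions
        assert not net.graph.has_edge(0, 1)
        assert net.graph.has_edge(0, 2)

    def test_weights_and_lengths(self):
        corr, occ, nm = self._inputs()
        corr.values[0, 2] = corr.values[2, 0] = -0.5
        net = build_network(corr, occ, nm, exclusions=set())
        d = net.graph[0][2]
        assert d["weight"] == pytest.approx(0.5)
        assert d["length"] == pytest.approx(-np.log(0.5))

    def test_zero_correlation_edge_dropped(self):
        corr, occ, nm = self._inputs()
        corr.values[0, 2] = corr.values[2, 0] = 0.0
        with pytest.warns(UserWarning, match="zero-correlation"):
            net = build_network(corr, occ, nm, exclusions=set())
        assert not net.graph.has_edge(0, 2)

    def test_raising_threshold_never_adds_edges(self, small_system):
        spec, geometry, trajectories = small_system
        corr = correlation_matrix(trajectories[0])
        occ = contact_occupancy(trajectories[0])
        loose = build_network(corr, occ, geometry.node_map, occ_threshold=0.5)
        tight = build_network(corr, occ, geometry.node_map, occ_threshold=0.9)
        assert set(tight.graph.edges) <= set(loose.graph.edges)

    def test_planted_contact_graph_recovered(self, small_networks, small_system):
        spec, geometry, _ = small_system
        expected = {
            p for p in spec.planted_contacts()
            if p not in geometry.node_map.covalent_pairs()
        }
        got = {tuple(sorted(e)) for e in small_networks[0].graph.edges}
        assert got == expected


class TestConsensus:
    def test_majority_vote(self, small_networks):
        cons = consensus_network(small_networks)
        # every planted edge is stable across replicates here
        assert cons.n_edges == small_networks[0].n_edges
        for u, v, d in cons.graph.edges(data=True):
            ws = [n.graph[u][v]["weight"] for n in small_networks]
            assert d["weight"] == pytest.approx(np.mean(ws))

    def test_minority_edge_dropped(self):
        import networkx as nx

        g1 = nx.Graph([(0, 1, {"weight": 0.5, "length": 0.7, "occupancy": 1.0})])
        g1.add_nodes_from(range(3))
        g2 = nx.Graph()
        g2.add_nodes_from(range(3))
        g3 = nx.Graph()
        g3.add_nodes_from(range(3))
        nets = [graph_network(g) for g in (g1, g2, g3)]
        cons = consensus_network(nets)
        assert cons.n_edges == 0


def _oracle_betweenness(g):
    """Independent betweenness via scipy shortest paths (unique-path
    graphs only): count, for every node pair, the interior nodes and the
    edges of the single shortest path."""
    n = g.number_of_nodes()
    rows, cols, data = [], [], []
    for u, v, d in g.edges(data=True):
        rows += [u, v]
        cols += [v, u]
        data += [d["length"], d["length"]]
    mat = sp.csr_matrix((data, (rows, cols)), shape=(n, n))
    dist, pred = csgraph.dijkstra(mat, directed=False, return_predecessors=True)
    node_count = np.zeros(n)
    edge_count = {tuple(sorted(e)): 0 for e in g.edges}
    n_pairs = 0
    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(dist[s, t]):
                continue
            n_pairs += 1
            node = t
            while node != s:
                prev = pred[s, node]
                edge_count[tuple(sorted((prev, node)))] += 1
                if prev != s:
                    node_count[prev] += 1
                node = prev
    node_bc = node_count * 2.0 / ((n - 1) * (n - 2))
    edge_bc = {e: c * 2.0 / (n * (n - 1)) for e, c in edge_count.items()}
    return node_bc, edge_bc


class TestNetworkSummary:
    def test_three_node_path(self):
        import networkx as nx

        g = nx.Graph([(0, 1), (1, 2)])
        s = network_summary(graph_network(g))
        assert (s.n_nodes, s.n_edges, s.max_degree) == (3, 2, 2)
        assert s.avg_degree == pytest.approx(4 / 3)

    def test_star_center_betweenness_is_one(self):
        import networkx as nx

        g = nx.star_graph(5)
        s = network_summary(graph_network(g))
        assert s.max_node_betweenness == pytest.approx(1.0)

    def test_average_degree_identity(self, small_networks):
        s = network_summary(small_networks[0])
        assert s.avg_degree == pytest.approx(2 * s.n_edges / s.n_nodes, abs=1e-9)
        assert s.max_degree >= s.avg_degree

    def test_empty_network_warns(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(3))
        with pytest.warns(UserWarning, match="no edges"):
            s = network_summary(graph_network(g))
        assert s.n_edges == 0 and s.max_degree == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_betweenness_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_length_graph(rng, n_max=20)
        if g.number_of_edges() < 2:
            pytest.skip("degenerate draw")
        net = graph_network(g)
        s = network_summary(net)
        node_bc, edge_bc = _oracle_betweenness(g)
        assert s.max_node_betweenness == pytest.approx(node_bc.max(), abs=1e-9)
        assert s.max_edge_betweenness == pytest.approx(
            max(edge_bc.values()), abs=1e-9
        )

    def test_weighted_degree_sums_incident_strengths(self, small_networks):
        net = small_networks[0]
        table = weighted_degrees(net)
        i = 0
        expected = sum(d["weight"] for _, _, d in net.graph.edges(i, data=True))
        assert table.loc[table["node"] == net.label(i), "weighted_degree"].iloc[0] == pytest.approx(expected)
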