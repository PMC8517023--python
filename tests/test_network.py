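"""Correlation matrices, persistence graphs and community detection."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from kv7pip2.core import Selection
from kv7pip2.network import (CorrelationNetwork, build_network,
                             community_report, correlation_matrix,
                             covering_count, detect_communities,
                             persistence_graph, _modularity)
from kv7pip2.synth_traj import (PlantedCommunities, partition_by_tags,
                                simulate_correlated_trajectory)

from conftest import point_traj

COUPLING_TAGS = ("S4", "S4S5_LINKER", "S6", "PRE_HELIX_A")


# --- correlation matrix -----------------------------------------------------


class TestCorrelationMatrix:
    def test_copied_motion_is_plus_one(self, rng):
        base = rng.normal(size=(20, 1, 3))
        coords = np.concatenate([base, base + [5.0, 0, 0]], axis=1)
        C = correlation_matrix(point_traj(coords), Selection(), align=False)
        assert C[0, 1] == pytest.approx(1.0)

    def test_mirrored_motion_is_minus_one(self, rng):
        base = rng.normal(size=(20, 1, 3))
        coords = np.concatenate([base, -base + [5.0, 0, 0]], axis=1)
        C = correlation_matrix(point_traj(coords), Selection(), align=False)
        assert C[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_summation_oracle(self, rng):
        coords = rng.normal(size=(5, 3, 3)) * 2
        C = correlation_matrix(point_traj(coords), Selection(), align=False)
        d = coords - coords.mean(axis=0)
        for i, j in itertools.product(range(3), repeat=2):
            num = sum(d[t, i] @ d[t, j] for t in range(5))
            den = np.sqrt(sum(d[t, i] @ d[t, i] for t in range(5))
                          * sum(d[t, j] @ d[t, j] for t in range(5)))
            assert abs(C[i, j] - num / den) < 1e-10

    def test_invariant_under_global_rigid_motion(self):
        # fluctuations small relative to the structure, as for real Calpha
        rng = np.random.default_rng(42)
        coords = rng.normal(size=(15, 6, 3)) * 0.3 + np.array([10.0, 0, 0])
        C0 = correlation_matrix(point_traj(coords), Selection(), align=True)
        moved = np.empty_like(coords)
        for t in range(15):
            R = Rotation.from_euler("xyz", rng.uniform(-20, 20, 3),
                                    degrees=True).as_matrix()
            moved[t] = coords[t] @ R.T + rng.normal(size=3) * 5
        C1 = correlation_matrix(point_traj(moved), Selection(), align=True)
        np.testing.assert_allclose(C0, C1, atol=1e-8)

    def test_zero_variance_node_flagged_and_zeroed(self, rng):
        coords = rng.normal(size=(10, 2, 3))
        coords[:, 1] = [1.0, 2.0, 3.0]       # frozen node
        with pytest.warns(RuntimeWarning):
            C = correlation_matrix(point_traj(coords), Selection(), align=False)
        assert C[0, 1] == 0.0 and C[1, 1] == 1.0


# --- persistence graph ------------------------------------------------------


class TestPersistenceGraph:
    def test_fixed_pair_within_cutoff(self):
        coords = np.zeros((8, 2, 3))
        coords[:, 1, 0] = 4.0
        traj = point_traj(coords)
        P, edges = persistence_graph(traj, Selection(), cutoff=4.5,
                                     fraction=0.75)
        assert P[0, 1] == 1.0 and edges == [(0, 1)]

    def test_square_wave_fraction_threshold(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = 4.0
        coords[7:, 1, 0] = 6.0               # within cutoff 70% of frames
        traj = point_traj(coords)
        _, edges_75 = persistence_graph(traj, Selection(), fraction=0.75)
        _, edges_50 = persistence_graph(traj, Selection(), fraction=0.5)
        assert edges_75 == [] and edges_50 == [(0, 1)]

    def test_matrix_symmetric_diagonal_free(self, rng):
        traj = point_traj(rng.normal(size=(6, 5, 3)) * 3)
        P, _ = persistence_graph(traj, Selection(), cutoff=3.0, fraction=0.5)
        np.testing.assert_array_equal(P, P.T)
        assert np.all(np.diag(P) == 0)

    def test_edge_set_shrinks_with_fraction(self, rng):
        traj = point_traj(rng.normal(size=(12, 6, 3)) * 2.5)
        prev = None
        for frac in (0.25, 0.5, 0.75, 1.0):
            _, edges = persistence_graph(traj, Selection(), cutoff=4.0,
                                         fraction=frac)
            if prev is not None:
                assert set(edges) <= set(prev)
            prev = edges

    def test_residue_heavy_mode_uses_min_heavy_distance(self):
        # two 2-atom residues: closest heavy pair 4.0, CA-CA pair 7.0
        coords = np.zeros((3, 4, 3))
        coords[:, 1, 0] = 3.0                # side atom of residue 1
        coords[:, 2, 0] = 7.0                # side atom of residue 2
        coords[:, 3, 0] = 10.0
        traj = point_traj(coords, names=["CA", "CB", "CB", "CA"],
                          resids=[1, 1, 2, 2])
        calpha = Selection.make(names=["CA"])
        _, edges_ca = persistence_graph(traj, calpha, cutoff=4.5)
        _, edges_rh = persistence_graph(traj, calpha, cutoff=4.5,
                                        mode="residue_heavy")
        assert edges_ca == [] and edges_rh == [(0, 1)]


# --- community detection ----------------------------------------------------


def _partitions(items):
    items = list(items)
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in _partitions(items[1:]):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def _net_from_graph(G):
    n = G.number_of_nodes()
    for u, v in G.edges:
        c = G.edges[u, v].setdefault("strength", 0.5)
        G.edges[u, v]["distance"] = -np.log(max(c, 1e-6))
    return CorrelationNetwork(nodes=[("A", i, "OTHER") for i in range(n)],
                              C=np.eye(n), persistence=np.zeros((n, n)),
                              edges=list(G.edges), graph=G)


def _small_graphs():
    graphs = [nx.complete_graph(5), nx.path_graph(6), nx.cycle_graph(8),
              nx.star_graph(6), nx.barbell_graph(4, 0)]
    g = nx.Graph()
    for off in (0, 4):
        for i, j in itertools.combinations(range(off, off + 4), 2):
            g.add_edge(i, j, strength=0.9)
    g.add_edge(0, 4, strength=0.05)
    graphs.append(g)
    r = np.random.default_rng(0)
    for _ in range(8):
        n = int(r.integers(5, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(r.integers(10 ** 6)))
        if g.number_of_edges() == 0:
            continue
        for u, v in g.edges:
            g.edges[u, v]["strength"] = float(r.uniform(0.05, 0.95))
        graphs.append(g)
    return graphs


class TestDetectCommunities:
    def test_two_cliques_weak_bridge_split(self):
        G = nx.Graph()
        for off in (0, 5):
            for i, j in itertools.combinations(range(off, off + 5), 2):
                G.add_edge(i, j, strength=0.9)
        G.add_edge(0, 5, strength=0.02)
        net = _net_from_graph(G)
        partition, q = detect_communities(net)
        comms = {frozenset(c) for c in net.communities()}
        assert comms == {frozenset(range(5)), frozenset(range(5, 10))}
        assert q > 0.3

    def test_uniform_complete_graph_single_community(self):
        net = _net_from_graph(nx.complete_graph(6))
        partition, q = detect_communities(net)
        assert len(set(partition.values())) == 1
        assert q == 0.0

    def test_edgeless_graph_singletons(self):
        G = nx.Graph()
        G.add_nodes_from(range(4))
        net = _net_from_graph(G)
        partition, q = detect_communities(net)
        assert len(set(partition.values())) == 4 and q == 0.0

    @pytest.mark.parametrize("gi", range(14))
    def test_matches_exhaustive_modularity_on_small_graphs(self, gi):
        graphs = _small_graphs()
        if gi >= len(graphs):
            pytest.skip("fewer generated graphs")
        G = graphs[gi]
        net = _net_from_graph(G)
        _, q = detect_communities(net)
        q_best = max(_modularity(G, [set(p) for p in parts])
                     for parts in _partitions(list(G.nodes)))
        assert q == pytest.approx(q_best, abs=1e-9)

    def test_deterministic(self):
        g1 = _small_graphs()[5]
        g2 = _small_graphs()[5]
        p1, q1 = detect_communities(_net_from_graph(g1))
        p2, q2 = detect_communities(_net_from_graph(g2))
        assert p1 == p2 and q1 == q2


# --- planted-community round trips ------------------------------------------


def _interface_network(toy_system, groups, seed, coupling=0.0, noise=0.1):
    part = partition_by_tags(toy_system, groups)
    comm = PlantedCommunities(part, {g: 1.0 for g in part},
                              noise_amplitude=noise, coupling=coupling)
    traj = simulate_correlated_trajectory(toy_system, comm, None, 300,
                                          seed=seed)
    net = build_network(traj, toy_system.vsd_pore_selection("A"),
                        cutoff=13.0, align=False)
    detect_communities(net)
    return net


class TestPlantedRoundTrips:
    def test_coupled_single_community_covers_vsd_pore(self, toy_system):
        net = _interface_network(toy_system, {"vsd_pore": COUPLING_TAGS},
                                 seed=2)
        assert covering_count(net, COUPLING_TAGS) == 1

    def test_decoupled_three_way_split(self, toy_system):
        net = _interface_network(
            toy_system, {"g1": ("S4", "S4S5_LINKER"), "g2": ("S6",),
                         "g3": ("PRE_HELIX_A",)}, seed=3)
        assert covering_count(net, COUPLING_TAGS) == 3

    def test_two_group_plant_recovered_exactly(self, toy_system):
        """Adjusted Rand index 1 for a clean 2-community plant (SNR 10)."""
        net = _interface_network(
            toy_system, {"g1": ("S4", "S4S5_LINKER"),
                         "g2": ("S6", "PRE_HELIX_A")}, seed=4)
        truth = [0 if t in ("S4", "S4S5_LINKER") else 1
                 for (_, _, t) in net.nodes]
        pred = [net.partition[i] for i in range(len(net.nodes))]
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, pred) == 1.0

    def test_report_rows_partition_all_nodes(self, toy_system):
        net = _interface_network(toy_system, {"vsd_pore": COUPLING_TAGS},
                                 seed=2)
        report = community_report(net, toy_system.topology)
        tags_in_report = set(report["tag"])
        assert tags_in_report == set(COUPLING_TAGS)
        n_by_tag = {t: sum(1 for (_, _, tag) in net.nodes if tag == t)
                    for t in tags_in_report}
        assert sum(n_by_tag.values()) == len(net.nodes)
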