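import numpy as np
import pandas as pd
import pytest
import networkx as nx

from rinpipe import observables as obs
from rinpipe.network import (
    InteractionNetwork,
    betweenness,
    centrality_histogram,
    contact_network,
    cross_correlation,
    degree_and_hubs,
    edge_weight,
    floyd_warshall,
    weight_edges,
)
from rinpipe.structure import select_atoms
from rinpipe.synthetic import (
    ChainSpec,
    CovarianceSpec,
    build_hub_system,
    build_ideal_chain,
    sample_gaussian_ensemble,
)
from conftest import make_points_ensemble

EDGE_COLS = [
    "i", "j", "resid_i", "resid_j", "n_ij", "i_ij", "c_ij", "w_ij",
    "in_path_graph",
]


def net_from_edges(edge_list, n):
    """Weighted path-graph network from (i, j, w) triples."""
    rows = [
        {
            "i": i, "j": j, "resid_i": i + 1, "resid_j": j + 1,
            "n_ij": 1, "i_ij": 10.0, "c_ij": np.exp(-w), "w_ij": w,
            "in_path_graph": True,
        }
        for i, j, w in edge_list
    ]
    return InteractionNetwork(
        np.arange(1, n + 1), pd.DataFrame(rows, columns=EDGE_COLS),
        2.5, 4.5, 0.5,
    )


def random_net(rng, n, p=0.5, weighted=True, connected=False):
    while True:
        edges = [
            (i, j, float(rng.uniform(0.5, 2.0)) if weighted else 1.0)
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        if not connected:
            break
        g = nx.Graph([(i, j) for i, j, _ in edges])
        g.add_nodes_from(range(n))
        if nx.is_connected(g):
            break
    return net_from_edges(edges, n)


def nx_graph(net):
    g = nx.Graph()
    g.add_nodes_from(range(net.n_nodes))
    for r in net.edges.itertuples():
        g.add_edge(r.i, r.j, weight=r.w_ij)
    return g


def brute_force_betweenness(g, n):
    """Raw betweenness by exhaustive shortest-path enumeration."""
    raw = np.zeros(n)
    for j in range(n):
        for k in range(j + 1, n):
            try:
                paths = list(nx.all_shortest_paths(g, j, k, weight="weight"))
            except nx.NetworkXNoPath:
                continue
            for i in range(n):
                if i in (j, k):
                    continue
                raw[i] += sum(1 for p in paths if i in p[1:-1]) / len(paths)
    return raw


class TestCrossCorrelation:
    def test_diagonal_is_one(self, noisy_helix):
        c = cross_correlation(noisy_helix)
        assert np.allclose(np.diag(c.matrix), 1.0)
        assert np.allclose(c.matrix, c.matrix.T)

    def test_identical_displacements_give_unity(self):
        rng = np.random.default_rng(0)
        disp = rng.normal(size=(50, 1, 3))
        base = np.array([[[0.0, 0, 0], [10.0, 0, 0]]])
        coords = base + np.concatenate([disp, disp], axis=1)
        ens = make_points_ensemble(coords, names=["CA", "CA"])
        c = cross_correlation(ens)
        assert c.matrix[0, 1] == pytest.approx(1.0)

    def test_anticorrelated_pair_recovery(self):
        """Planted negative cross-block correlation is recovered."""
        ref = build_ideal_chain(ChainSpec(12))
        cov = CovarianceSpec(
            base_sigma=0.5, cross_block=[([2], [8], 0.8, -1)]
        )
        ens = sample_gaussian_ensemble(ref, cov, 2000, seed=9)
        c = cross_correlation(ens)
        assert c.matrix[2, 8] == pytest.approx(-0.8, abs=0.05)

    def test_static_residue_warns_and_zeroes(self):
        rng = np.random.default_rng(1)
        moving = rng.normal(size=(20, 1, 3)) + [[5.0, 0, 0]]
        static = np.zeros((20, 1, 3))
        ens = make_points_ensemble(
            np.concatenate([moving, static], axis=1), names=["CA", "CA"]
        )
        with pytest.warns(UserWarning, match="static"):
            c = cross_correlation(ens)
        assert c.matrix[0, 1] == 0.0
        assert c.matrix[1, 1] == 1.0


class TestContactNetwork:
    def make_triplet(self):
        """Three 4-atom residues; residues 1 and 3 in close contact."""
        res1 = np.array([[0.0, 0, 0], [1.0, 0, 0], [0, 1.0, 0], [1.0, 1.0, 0]])
        res2 = res1 + [60.0, 0, 0]  # far away (sequence neighbour anyway)
        res3 = res1 + [0.0, 3.0, 0]  # 16 pairs, several within 4.5 A
        coords = np.concatenate([res1, res2, res3])[None]
        return make_points_ensemble(
            coords, resids=[1] * 4 + [2] * 4 + [3] * 4
        )

    def test_hand_counted_strength(self):
        ens = self.make_triplet()
        # hand count: pairs (a in res1, b in res3) with |a-b| <= 4.5:
        # all y-offsets are 2 or 3, x-offsets 0 or 1 -> all 16 pairs
        net = contact_network(ens, norm_table={"UNK": 16})
        assert len(net.edges) == 1
        edge = net.edges.iloc[0]
        assert edge["n_ij"] == 16
        assert edge["i_ij"] == pytest.approx(100.0)

    def test_dataset_derived_normalization(self):
        ens = self.make_triplet()
        net = contact_network(ens)
        # N is the max observed n_ij for the residue type -> I = 100
        assert net.edges.iloc[0]["i_ij"] == pytest.approx(100.0)

    def test_distant_residues_no_edge(self):
        coords = np.array([[[0.0, 0, 0], [50.0, 0, 0]]])
        ens = make_points_ensemble(coords, resids=[1, 3])
        net = contact_network(ens)
        assert len(net.edges) == 0

    def test_i_min_cutoff_boundary(self):
        ens = self.make_triplet()
        # force I = 100*16/sqrt(N*N); N such that I just misses 2.5
        n_drop = 16 * 100 / 2.4  # -> I = 2.4, dropped
        n_keep = 16 * 100 / 2.5  # -> I = 2.5, retained (>= I_min)
        assert len(contact_network(ens, norm_table={"UNK": n_drop}).edges) == 0
        assert len(contact_network(ens, norm_table={"UNK": n_keep}).edges) == 1

    def test_sequence_neighbors_excluded(self):
        res1 = np.zeros((1, 3))
        res2 = res1 + [3.0, 0, 0]
        ens = make_points_ensemble(
            np.concatenate([res1, res2])[None], resids=[1, 2]
        )
        assert len(contact_network(ens).edges) == 0

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            contact_network(
                make_points_ensemble(np.zeros((1, 1, 3)), elements=["H"])
            )


class TestEdgeWeights:
    def test_printed_value_at_half(self):
        assert round(edge_weight(0.5), 2) == 0.69

    def test_perfect_correlation_zero_weight(self):
        assert edge_weight(1.0) == 0.0
        assert edge_weight(-1.0) == 0.0

    def test_below_floor_removed_from_path_graph(self, noisy_helix):
        fitted = obs.superpose(noisy_helix)
        corr = cross_correlation(fitted)
        avg = obs.average_structure(fitted)
        net = contact_network(avg)
        weighted = weight_edges(net, corr, c_floor=0.5)
        dropped = weighted.edges[~weighted.edges["in_path_graph"]]
        assert (dropped["c_ij"].abs() < 0.5).all()
        kept = weighted.edges[weighted.edges["in_path_graph"]]
        assert np.allclose(kept["w_ij"], -np.log(kept["c_ij"].abs()))

    def test_mismatched_residues_raise(self, noisy_helix):
        fitted = obs.superpose(noisy_helix)
        corr = cross_correlation(fitted)
        avg = obs.average_structure(fitted)
        net = contact_network(avg)
        bad = InteractionNetwork(
            net.resids + 100, net.edges, net.i_min, net.contact_cutoff
        )
        with pytest.raises(ValueError):
            weight_edges(bad, corr)


class TestFloydWarshall:
    def test_unit_square_ties(self):
        net = net_from_edges(
            [(0, 1, 1.0), (1, 2, 1.0), (2, 3, 1.0), (3, 0, 1.0)], 4
        )
        pm = floyd_warshall(net)
        assert pm.dist[0, 2] == pytest.approx(2.0)
        assert pm.counts[0, 2] == 2  # two equal-length routes

    def test_disconnected_pair(self):
        net = net_from_edges([(0, 1, 1.0)], 3)
        pm = floyd_warshall(net)
        assert np.isinf(pm.dist[0, 2])
        assert pm.counts[0, 2] == 0

    def test_negative_weight_rejected(self):
        net = net_from_edges([(0, 1, -0.5)], 2)
        with pytest.raises(ValueError):
            floyd_warshall(net)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_dijkstra(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 13))
        net = random_net(rng, n, weighted=bool(trial % 2))
        pm = floyd_warshall(net)
        g = nx_graph(net)
        for s in range(n):
            lengths = nx.single_source_dijkstra_path_length(g, s)
            for t in range(n):
                ref = lengths.get(t, np.inf)
                if np.isinf(ref):
                    assert np.isinf(pm.dist[s, t])
                else:
                    assert pm.dist[s, t] == pytest.approx(ref, abs=1e-9)


class TestBetweenness:
    def test_three_node_path(self):
        net = net_from_edges([(0, 1, 1.0), (1, 2, 1.0)], 3)
        raw, norm = betweenness(floyd_warshall(net))
        assert raw.tolist() == [0.0, 1.0, 0.0]
        assert norm.tolist() == [0.0, 0.5, 0.0]

    def test_leaf_is_zero(self):
        rng = np.random.default_rng(5)
        net = random_net(rng, 7, connected=True)
        edges = net.edges
        raw, _ = betweenness(floyd_warshall(net))
        degree = np.zeros(7)
        for r in edges.itertuples():
            degree[r.i] += 1
            degree[r.j] += 1
        assert np.allclose(raw[degree <= 1], 0.0)

    def test_small_n_all_zero(self):
        net = net_from_edges([(0, 1, 1.0)], 2)
        raw, norm = betweenness(floyd_warshall(net))
        assert np.allclose(raw, 0) and np.allclose(norm, 0)

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_enumeration_oracle(self, trial):
        rng = np.random.default_rng(2000 + trial)
        n = int(rng.integers(3, 9))
        net = random_net(rng, n, weighted=bool(trial % 2))
        raw, norm = betweenness(floyd_warshall(net))
        ref = brute_force_betweenness(nx_graph(net), n)
        assert np.allclose(raw, ref, atol=1e-9)
        assert np.allclose(norm, ref / ((n - 1) * (n - 2)), atol=1e-9)

    @pytest.mark.parametrize("n_leaves", [3, 5, 8])
    def test_star_closed_form(self, n_leaves):
        """Tree identity: every leaf pair routes through the star center."""
        net = net_from_edges([(0, k, 1.0) for k in range(1, n_leaves + 1)], n_leaves + 1)
        raw, _ = betweenness(floyd_warshall(net))
        assert raw[0] == pytest.approx(n_leaves * (n_leaves - 1) / 2)
        assert np.allclose(raw[1:], 0.0)

    def test_path_closed_form(self):
        n = 7
        net = net_from_edges([(k, k + 1, 1.0) for k in range(n - 1)], n)
        raw, _ = betweenness(floyd_warshall(net))
        expected = [k * (n - 1 - k) for k in range(n)]
        assert np.allclose(raw, expected)


class TestDegreeAndHubs:
    def test_complete_graph_all_hubs(self):
        net = net_from_edges(
            [(i, j, 1.0) for i in range(5) for j in range(i + 1, 5)], 5
        )
        prof = degree_and_hubs(net, hub_min=4)
        assert (prof.table["degree"] == 4).all()
        assert prof.table["hub"].all()

    def test_isolated_and_low_degree_not_hubs(self):
        net = net_from_edges([(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)], 5)
        prof = degree_and_hubs(net, hub_min=4)
        t = prof.table
        assert t.loc[4, "degree"] == 0 and not t.loc[4, "hub"]
        assert t.loc[0, "degree"] == 3 and not t.loc[0, "hub"]

    def test_closeness_within_component(self):
        net = net_from_edges([(0, 1, 2.0), (1, 2, 2.0)], 4)
        prof = degree_and_hubs(net, paths=floyd_warshall(net))
        t = prof.table
        assert t.loc[1, "closeness"] == pytest.approx(2 / 4.0)
        assert t.loc[0, "closeness"] == pytest.approx(2 / 6.0)
        assert t.loc[3, "closeness"] == 0.0


class TestHistogram:
    def test_conservation(self):
        rng = np.random.default_rng(0)
        vals = rng.random(37)
        _, freq = centrality_histogram(vals, 10)
        assert freq.sum() == 37

    def test_identical_values_single_bin(self):
        edges, freq = centrality_histogram(np.zeros(9), 10)
        assert len(freq) == 1 and freq[0] == 9

    def test_hand_binned_fixture(self):
        vals = np.array([0.0, 0.1, 0.2, 0.9, 1.0])
        edges, freq = centrality_histogram(vals, 2)
        assert freq.tolist() == [3, 2]
        assert edges[0] == 0.0 and edges[-1] == 1.0


class TestFiltering:
    def test_raising_thresholds_never_adds_edges(self, noisy_helix):
        fitted = obs.superpose(noisy_helix)
        corr = cross_correlation(fitted)
        avg = obs.average_structure(fitted)
        loose = contact_network(avg, i_min=1.0)
        tight = contact_network(avg, i_min=5.0)
        assert len(tight.edges) <= len(loose.edges)
        pairs_t = set(map(tuple, tight.edges[["i", "j"]].to_numpy()))
        pairs_l = set(map(tuple, loose.edges[["i", "j"]].to_numpy()))
        assert pairs_t <= pairs_l
        w_lo = weight_edges(loose, corr, c_floor=0.3)
        w_hi = weight_edges(loose, corr, c_floor=0.7)
        kept_hi = w_hi.edges["in_path_graph"].sum()
        kept_lo = w_lo.edges["in_path_graph"].sum()
        assert kept_hi <= kept_lo


def test_planted_hub_recovery_small():
    """A planted high-contact/high-correlation residue tops the network."""
    ens, hub = build_hub_system(n_frames=400, seed=3)
    ca = select_atoms(ens.topology, "name CA")
    fitted = obs.superpose_to_mean(ens, ca)
    corr = cross_correlation(fitted)
    avg = obs.average_structure(fitted)
    net = weight_edges(contact_network(avg), corr, c_floor=0.5)
    prof = degree_and_hubs(net, hub_min=4, paths=floyd_warshall(net))
    t = prof.table
    row = t[t["resid"] == hub].iloc[0]
    assert row["degree"] == t["degree"].max()
    assert row["hub"]
    rank = int((t["betweenness"] > row["betweenness"]).sum()) + 1
    assert rank <= 3
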