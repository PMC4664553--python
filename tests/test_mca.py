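"""Shortest paths, compactness, LPI, k-medoids, boundary repair,
modularity, split decisions and the full multiscale decomposition."""

import math

import networkx as nx
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from pfnet.mca import (
    MCAConfig,
    boundary_update,
    characteristic_alpha,
    compactness,
    compactness_significance,
    k_medoids_partition,
    k_split,
    lpi,
    modularity,
    run_mca,
    shortest_path_matrix,
    split_decision,
)
from pfnet.mca import _lpi_from_adjacency
from pfnet.random_planar import t2_random_planar

from _oracles import exhaustive_k_medoids_cost, floyd_warshall


def _unit_graph(edges):
    g = nx.Graph()
    g.add_edges_from((u, v, {"weight": 0.0}) for u, v in edges)  # length 1 each
    return g


class TestShortestPaths:
    def test_path_graph_distance(self):
        g = _unit_graph([("a", "b"), ("b", "c")])
        D, order = shortest_path_matrix(g, transform="unit")
        i, j = order.index("a"), order.index("c")
        assert D[i, j] == pytest.approx(2.0)

    def test_detour_around_heavy_edge(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.0)
        g.add_edge("b", "c", weight=0.0)
        g.add_edge("a", "c", weight=-4.0)  # length 1-|-4| would be negative
        with pytest.raises(ValueError):
            shortest_path_matrix(g)
        # with explicit lengths 1,1,5 via unit transform on a triangle
        g2 = nx.Graph()
        g2.add_edge("a", "b", weight=1)
        g2.add_edge("b", "c", weight=1)
        D, order = shortest_path_matrix(g2, transform="unit")
        # adding the heavy edge as a direct 5-length is bypassed by the detour
        g2.add_edge("a", "c", weight=1)
        D2, order2 = shortest_path_matrix(g2, transform="one_minus_abs")
        # unit-weight edges have length ~0 -> everything collapses near 0
        assert D2.max() < 1e-6

    @pytest.mark.parametrize("use_bf", [False, True])
    def test_matches_floyd_warshall_oracle(self, use_bf, rng):
        g = t2_random_planar(30, seed=3, weights=rng.uniform(0.1, 0.9, size=84))
        D, order = shortest_path_matrix(g, use_bellman_ford=use_bf)
        direct = np.full((30, 30), np.inf)
        np.fill_diagonal(direct, 0.0)
        idx = {u: i for i, u in enumerate(order)}
        for u, v, w in g.edges(data="weight"):
            direct[idx[u], idx[v]] = direct[idx[v], idx[u]] = 1 - abs(w)
        assert np.allclose(D, floyd_warshall(direct), atol=1e-9)

    def test_disconnected_pairs_infinite(self):
        g = _unit_graph([("a", "b"), ("c", "d")])
        D, order = shortest_path_matrix(g, transform="unit")
        assert np.isinf(D[order.index("a"), order.index("c")])


class TestCompactness:
    def test_star_hand_enumeration(self):
        # 10-node star, unit lengths: 9 center pairs at 1, 36 leaf pairs at 2
        g = _unit_graph([("c", f"l{i}") for i in range(9)])
        D, order = shortest_path_matrix(g, transform="unit")
        assert compactness(D, alpha=1.0) == pytest.approx(1.8 / math.log(10))

    def test_alpha_zero_is_mean_spd(self, rng):
        D = rng.uniform(1, 3, size=(8, 8))
        D = (D + D.T) / 2
        iu = np.triu_indices(8, 1)
        assert compactness(D, 0.0) == pytest.approx(D[iu].mean())

    def test_strictly_decreasing_in_alpha_above_e(self, rng):
        D = rng.uniform(1, 3, size=(10, 10))
        D = (D + D.T) / 2
        vals = [compactness(D, a) for a in np.linspace(0.1, 5, 20)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            compactness(np.zeros((1, 1)), 1.0)


class TestLpi:
    def test_path_walk_enumeration(self):
        g = _unit_graph([("a", "b"), ("b", "c")])
        L, order = lpi(g, epsilon=0.01)
        assert L[order.index("a"), order.index("c")] == pytest.approx(1.0)

    def test_triangle_walk_enumeration(self):
        L, order = lpi(_unit_graph([("a", "b"), ("b", "c"), ("a", "c")]), epsilon=0.01)
        off = L[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.03)

    def test_edgeless_graph_zero(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        L, _ = lpi(g)
        assert not L.any()


class TestKMedoids:
    def test_separated_blocks_recovered(self):
        D = np.full((8, 8), 10.0)
        D[:4, :4] = 1.0
        D[4:, 4:] = 1.0
        np.fill_diagonal(D, 0.0)
        labels = k_medoids_partition(D, 2)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[7]

    def test_k_out_of_range_rejected(self):
        D = np.zeros((5, 5))
        with pytest.raises(ValueError):
            k_medoids_partition(D, 1)
        with pytest.raises(ValueError):
            k_medoids_partition(D, 5)

    def test_objective_matches_exhaustive_optimum(self, rng):
        pts = rng.standard_normal((12, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = k_medoids_partition(D, 3)
        # recompute the attained objective from the labels' implied medoids
        cost = 0.0
        for l in np.unique(labels):
            mask = labels == l
            cost += D[np.ix_(mask, mask)].sum(axis=0).min()
        assert cost == pytest.approx(exhaustive_k_medoids_cost(D, 3), rel=1e-9)

    def test_deterministic(self, rng):
        D = rng.uniform(size=(15, 15))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        assert np.array_equal(k_medoids_partition(D, 3), k_medoids_partition(D, 3))


class TestBoundaryUpdate:
    def _k5_barbell(self):
        # two K5 blocks joined by a single bridge (4, 5)
        A = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for u in block:
                for v in block:
                    if u != v:
                        A[u, v] = 1
        A[4, 5] = A[5, 4] = 1
        return A, _lpi_from_adjacency(A, 0.01)

    def test_no_boundary_is_fixed_point(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[2, 3] = A[3, 2] = 1
        L = _lpi_from_adjacency(A, 0.01)
        labels = np.array([0, 0, 1, 1])
        assert np.array_equal(boundary_update(labels, A, L), labels)

    def test_mislabeled_bridge_endpoint_restored(self):
        A, L = self._k5_barbell()
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])  # node 4 with wrong block
        fixed = boundary_update(labels, A, L)
        assert list(fixed) == [0] * 5 + [1] * 5
        # direct evaluation of the LPI affinities driving the move
        assert L[4, :4].sum() > L[4, 5:].sum()

    def test_idempotent(self):
        A, L = self._k5_barbell()
        once = boundary_update(np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1]), A, L)
        assert np.array_equal(boundary_update(once, A, L), once)


class TestModularity:
    def test_two_disjoint_triangles_hand_value(self):
        g = _unit_graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        assert modularity(g, np.array([0, 0, 0, 1, 1, 1])) == pytest.approx(0.5)

    def test_single_community_zero(self):
        g = _unit_graph([(0, 1), (1, 2), (2, 3), (3, 0)])
        assert modularity(g, np.zeros(4, dtype=int)) == pytest.approx(0.0)

    def test_matches_networkx(self, rng):
        g = t2_random_planar(25, seed=5)
        labels = rng.integers(0, 3, size=25)
        order = sorted(g.nodes, key=str)
        comms = [
            {order[i] for i in np.where(labels == l)[0]} for l in range(3)
        ]
        comms = [c for c in comms if c]
        ref = nx.community.modularity(g, comms, weight=None)
        assert modularity(g, labels) == pytest.approx(ref, abs=1e-12)

    def test_planted_beats_random_labels(self):
        wins = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            # two planar blocks joined by a single bridge
            g = nx.disjoint_union(
                t2_random_planar(15, seed=seed), t2_random_planar(15, seed=1000 + seed)
            )
            g.add_edge(0, 15)
            A = nx.to_numpy_array(g, nodelist=range(30), weight=None)
            planted = np.array([0] * 15 + [1] * 15)
            random_labels = rng.permutation(planted)
            if modularity(A, planted) > modularity(A, random_labels):
                wins += 1
        assert wins >= 95


class TestKSplit:
    def _two_cliques(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        g.add_edge(0, 5)
        order = sorted(g.nodes, key=str)
        D, _ = shortest_path_matrix(
            nx.relabel_nodes(g, {u: str(u) for u in g.nodes}), transform="unit"
        )
        A = nx.to_numpy_array(g, nodelist=sorted(g.nodes, key=str), weight=None)
        return D, A, _lpi_from_adjacency(A, 0.01)

    def test_two_planted_cliques_split_at_two(self):
        D, A, L = self._two_cliques()
        labels, profile = k_split(D, A, L)
        assert labels is not None
        assert len(np.unique(labels)) == 2
        assert profile[2] == max(profile.values())

    def test_planted_modules_recovered(self, small_expression):
        from pfnet import MultiscaleNetworkModel

        res = MultiscaleNetworkModel(small_expression.expr, seed=11).fit()
        genes = [g for g in small_expression.expr.index]
        truth = small_expression.module_labels.loc[genes].to_numpy()
        in_module = truth > 0
        best = 0.0
        for a in res.hierarchy.alpha_grid:
            part = res.hierarchy.partition_at_alpha(a)
            pred = np.array([hash(part.get(g, "none")) for g in genes])
            best = max(best, adjusted_rand_score(truth[in_module], pred[in_module]))
        assert best >= 0.9

    def test_search_bounded_by_dk(self):
        D, A, L = self._two_cliques()
        _, profile = k_split(D, A, L, dk=3)
        best_k = max(profile, key=profile.get)
        assert max(profile) <= best_k + 3


class TestSplitDecisions:
    def test_accept_reject_and_strictness(self):
        assert split_decision(1.0, [1.2, 0.8], alpha=1.0)
        assert not split_decision(1.0, [1.2, 1.5], alpha=1.0)
        assert not split_decision(1.0, [1.0, 1.0], alpha=1.0)

    def test_child_identical_to_parent_has_no_characteristic_alpha(self):
        grid = np.geomspace(0.02, 10, 50)
        assert characteristic_alpha(2.0, 30, 2.0, 30, 10.0, grid) is None

    def test_tight_subcluster_attains_parent_alpha(self):
        grid = np.geomspace(0.02, 10, 50)
        # a child with essentially-zero internal distances beats the
        # parent at every grid alpha, so the characteristic alpha is the
        # parent's bound
        a = characteristic_alpha(5.0, 50, 1e-9, 3, 10.0, grid)
        assert a == pytest.approx(grid.max())

    def test_matches_direct_grid_evaluation(self):
        grid = np.geomspace(0.02, 10, 50)
        spd_o, n_o, spd_l, n_l, bound = 3.0, 40, 1.1, 12, 10.0
        a = characteristic_alpha(spd_o, n_o, spd_l, n_l, bound, grid)
        admissible = [
            al
            for al in grid
            if al <= bound
            and spd_l / np.log(n_l) ** al < spd_o / np.log(n_o) ** al
        ]
        assert a == pytest.approx(max(admissible))

    def test_shrinking_alpha_bound_never_raises_characteristic(self):
        grid = np.geomspace(0.02, 10, 50)
        wide = characteristic_alpha(3.0, 40, 1.5, 12, 10.0, grid)
        narrow = characteristic_alpha(3.0, 40, 1.5, 12, 1.0, grid)
        assert narrow is None or (wide is not None and narrow <= wide)


class TestCompactnessSignificance:
    def test_whole_parent_not_significant(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = rng.uniform(0.3, 0.9, size=84)
            g = t2_random_planar(30, seed=seed, weights=w)
            D, order = shortest_path_matrix(g)
            nu = compactness(D, 1.0)
            p = compactness_significance(w, 30, 30, nu, 1.0, seed=seed)
            hits += p > 0.05
        assert hits >= 19

    def test_planted_tight_cluster_significant(self):
        # sparse ring with an embedded strong near-clique
        g = nx.cycle_graph(40)
        nx.set_edge_attributes(g, 0.3, "weight")
        for u in range(5):
            for v in range(u + 1, 5):
                g.add_edge(u, v, weight=0.95)
        D, order = shortest_path_matrix(g)
        members = [order.index(str(i)) if str(i) in order else order.index(i) for i in range(5)]
        sub = D[np.ix_(members, members)]
        nu = compactness(sub, 1.0)
        w = [d["weight"] for _, _, d in g.edges(data=True)]
        p = compactness_significance(w, 40, 5, nu, 1.0, seed=0)
        assert p <= 0.05

    def test_deterministic_given_seed(self):
        w = np.random.default_rng(0).uniform(0.2, 0.8, size=84)
        args = (w, 30, 8, 0.5, 1.0)
        assert compactness_significance(*args, seed=7) == compactness_significance(
            *args, seed=7
        )

    def test_tiny_cluster_p_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert compactness_significance([0.5], 10, 2, 0.1, 1.0, seed=0) == 1.0


class TestRunMca:
    def test_homogeneous_block_stays_single_root(self):
        g = t2_random_planar(12, seed=2, weights=np.full(30, 0.5))
        hier = run_mca(g, MCAConfig(seed=0, n_rand=30))
        sig = [
            c
            for c in hier.clusters.values()
            if c.parent and c.p_value is not None and c.p_value <= 0.05
        ]
        # a uniform triangulation has no significantly compact substructure
        assert len(sig) <= 1

    def test_structural_contract_children_partition_parent(self, small_expression):
        from pfnet import MultiscaleNetworkModel

        res = MultiscaleNetworkModel(small_expression.expr, seed=11).fit()
        hier = res.hierarchy
        for c in hier.clusters.values():
            if c.children:
                child_nodes = [n for k in c.children for n in hier.clusters[k].nodes]
                assert sorted(map(str, child_nodes)) == sorted(map(str, c.nodes))
            if c.parent is not None:
                assert set(c.nodes) <= set(hier.clusters[c.parent].nodes)

    def test_two_level_hierarchy_recovered(self):
        from pfnet import MultiscaleNetworkModel
        from pfnet.synthetic import PlantedDesign, generate_expression

        d = PlantedDesign(
            n_genes=72,
            n_samples=300,
            module_sizes=(12,) * 6,
            super_groups=((0, 1, 2), (3, 4, 5)),
            loading=0.5,
            super_loading=0.6,
            seed=21,
        )
        data = generate_expression(d)
        res = MultiscaleNetworkModel(data.expr, seed=21).fit()
        hier = res.hierarchy
        genes = list(data.expr.index)
        sup = data.super_labels.loc[genes].to_numpy()
        sub = data.module_labels.loc[genes].to_numpy()
        best_sup = best_sub = 0.0
        for a in hier.alpha_grid:
            part = hier.partition_at_alpha(a)
            lab = np.array([hash(part.get(g, "x")) for g in genes])
            best_sup = max(best_sup, adjusted_rand_score(sup, lab))
            best_sub = max(best_sub, adjusted_rand_score(sub, lab))
        assert best_sup >= 0.9
        assert best_sub >= 0.8
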