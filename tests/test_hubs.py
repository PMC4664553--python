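"""Within-cluster connectivity, validity indices, scale grouping and
hub significance."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pfnet.hubs import (
    combined_rank_score,
    group_scales,
    hub_pvalue_per_scale,
    hub_significance,
    intersect_multiscale_hubs,
    multiscale_hub_statistic,
    validity_indices,
    within_cluster_connectivity,
)
from pfnet.random_planar import t2_random_planar

from _oracles import silhouette_by_hand


class TestConnectivity:
    def test_triangle_cluster_hand_value(self):
        g = nx.Graph()
        for u, v in [("a", "b"), ("b", "c"), ("a", "c")]:
            g.add_edge(u, v, weight=0.5)
        cw = within_cluster_connectivity(g, {"a": 1, "b": 1, "c": 1})
        assert (cw == 1.0).all()

    def test_node_with_all_neighbors_outside_cluster(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=0.9)
        cw = within_cluster_connectivity(g, {"a": 1, "b": 2})
        assert cw["a"] == 0.0

    def test_matches_bruteforce_loop_oracle(self, rng):
        g = t2_random_planar(30, seed=6, weights=rng.uniform(0.1, 1, 84))
        membership = {v: int(rng.integers(3)) for v in g.nodes}
        cw = within_cluster_connectivity(g, membership)
        for v in g.nodes:
            expected = sum(
                abs(d["weight"])
                for _, u, d in g.edges(v, data=True)
                if membership[u] == membership[v]
            )
            assert cw[v] == pytest.approx(expected)

    def test_columns_conserve_total_within_weight(self, rng):
        g = t2_random_planar(25, seed=2, weights=rng.uniform(0.1, 1, 69))
        membership = {v: int(v) % 2 for v in g.nodes}
        cw = within_cluster_connectivity(g, membership)
        total_within = sum(
            abs(d["weight"])
            for u, v, d in g.edges(data=True)
            if membership[u] == membership[v]
        )
        assert cw.sum() == pytest.approx(2 * total_within)


class TestValidityIndices:
    def test_perfect_separation(self):
        D = np.full((6, 6), 5.0)
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        out = validity_indices(np.array([0, 0, 0, 1, 1, 1]), D)
        assert out["silhouette"] == pytest.approx(1.0)
        assert out["dunn"] == np.inf

    def test_random_labels_near_zero_silhouette(self):
        sils = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            D = rng.uniform(size=(20, 20))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            labels = rng.integers(0, 2, 20)
            if len(np.unique(labels)) < 2 or min(np.bincount(labels)) < 2:
                continue
            sils.append(validity_indices(labels, D, n_perm=10, seed=seed)["silhouette"])
        assert abs(np.mean(sils)) < 0.1

    def test_silhouette_matches_hand_formula(self, rng):
        pts = rng.standard_normal((10, 2))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
        out = validity_indices(labels, D)
        assert out["silhouette"] == pytest.approx(silhouette_by_hand(D, labels), abs=1e-9)

    def test_singleton_only_clustering_rejected(self):
        D = np.ones((3, 3))
        np.fill_diagonal(D, 0)
        with pytest.raises(ValueError):
            validity_indices(np.array([0, 1, 2]), D)


class TestCombinedRankScore:
    def test_dominating_k_wins(self):
        table = pd.DataFrame(
            {"silhouette": [0.9, 0.3, 0.1], "dunn": [2.0, 1.0, 0.5]}, index=[2, 3, 4]
        )
        k, scores = combined_rank_score(table, n_phi=6)
        assert k == 2
        assert scores[2] == scores.min()

    def test_score_worsens_when_any_rank_worsens(self):
        base = pd.DataFrame({"a": [3.0, 2.0], "b": [3.0, 2.0]}, index=[2, 3])
        worse = pd.DataFrame({"a": [3.0, 2.0], "b": [2.0, 3.0]}, index=[2, 3])
        _, s1 = combined_rank_score(base, n_phi=5)
        _, s2 = combined_rank_score(worse, n_phi=5)
        assert s2[2] > s1[2]

    def test_toy_table_matches_hand_computation(self):
        # 4 indices x 5 candidate k; ranks computed by hand
        table = pd.DataFrame(
            {
                "silhouette": [0.5, 0.8, 0.6, 0.2, 0.1],
                "gamma": [1.0, 3.0, 2.0, 0.5, 0.2],
                "dunn": [0.3, 0.9, 0.7, 0.2, 0.1],
                "sep": [0.6, 0.5, 0.9, 0.3, 0.2],
            },
            index=[2, 3, 4, 5, 6],
        )
        k, scores = combined_rank_score(table, n_phi=6)
        # hand ranks for k=3: sil 1, gamma 1, dunn 1, sep 3 (0.9 > 0.6 > 0.5)
        assert k == 3
        assert scores[3] == pytest.approx(3 * np.log(1 / 5) + np.log(3 / 5))
        # hand ranks for k=4: sil 2, gamma 2, dunn 2, sep 1
        assert scores[4] == pytest.approx(3 * np.log(2 / 5) + np.log(1 / 5))

    def test_invariant_to_monotone_transform_of_one_index(self):
        rngv = np.random.default_rng(0)
        table = pd.DataFrame(
            {"a": rngv.uniform(size=6), "b": rngv.uniform(size=6)},
            index=range(2, 8),
        )
        t2 = table.copy()
        t2["a"] = np.exp(5 * t2["a"])  # strictly monotone
        assert combined_rank_score(table, 8)[0] == combined_rank_score(t2, 8)[0]


class TestGroupScales:
    def _profiles(self, rng, n_nodes=40, pattern=("X", "X", "Y", "Y", "X", "Y")):
        x = rng.uniform(0, 5, n_nodes)
        y = rng.uniform(0, 5, n_nodes) + 10
        cols = {}
        for i, p in enumerate(pattern):
            cols[f"a{i}"] = x if p == "X" else y
        return pd.DataFrame(cols)

    def test_duplicated_profiles_split_exactly(self, rng):
        cw = self._profiles(rng)
        groups = group_scales(cw, seed=0)
        assert len(groups) == 2
        sets = {frozenset(g) for g in groups}
        assert sets == {frozenset({"a0", "a1", "a4"}), frozenset({"a2", "a3", "a5"})}

    def test_invariant_to_column_order(self, rng):
        cw = self._profiles(rng)
        shuffled = cw[list(cw.columns)[::-1]]
        g1 = {frozenset(g) for g in group_scales(cw, seed=0)}
        g2 = {frozenset(g) for g in group_scales(shuffled, seed=0)}
        assert g1 == g2

    def test_few_scales_single_group(self, rng):
        cw = pd.DataFrame({"a": rng.uniform(size=5), "b": rng.uniform(size=5)})
        assert group_scales(cw) == [["a", "b"]]

    def test_three_planted_blocks_recovered(self):
        hits = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            protos = [rng.uniform(0, 1, 30), rng.uniform(5, 6, 30), rng.uniform(12, 13, 30)]
            cols = {}
            truth = []
            for i in range(9):
                block = i % 3
                truth.append(block)
                cols[f"a{i}"] = protos[block] + 0.05 * rng.standard_normal(30)
            groups = group_scales(pd.DataFrame(cols), seed=seed)
            if len(groups) == 3:
                found = {frozenset(g) for g in groups}
                want = {
                    frozenset(f"a{i}" for i in range(9) if i % 3 == b) for b in range(3)
                }
                hits += found == want
        assert hits >= 27


class TestHubPvalues:
    def test_zero_connectivity_near_one(self):
        p = hub_pvalue_per_scale(np.zeros(20), np.full(54, 0.5), seed=0)
        assert (p > 0.9).all()

    def test_monotone_nonincreasing_in_connectivity(self, rng):
        c = np.sort(rng.uniform(0, 10, 15))
        p = hub_pvalue_per_scale(c, rng.uniform(0.2, 0.9, 39), seed=3)
        assert (np.diff(p) <= 1e-12).all()

    def test_star_hub_detected(self):
        # connectivity far above anything a random triangulation produces
        c = np.full(30, 1.0)
        c[0] = 60.0
        p = hub_pvalue_per_scale(c, np.full(84, 0.7), n_s=100, seed=1)
        assert p[0] < 0.05
        assert p[1:].min() > 0.05

    def test_tiny_cluster_all_ones(self):
        assert (hub_pvalue_per_scale(np.zeros(2), [0.5], seed=0) == 1.0).all()


class TestCombinedStatistic:
    def test_all_ones_gives_zero(self):
        assert multiscale_hub_statistic([1.0, 1.0, 1.0]) == 0.0

    def test_printed_example(self):
        assert multiscale_hub_statistic([0.01, 0.001]) == pytest.approx(5.0)

    def test_additive_over_partition(self, rng):
        p = rng.uniform(0.001, 1, 10)
        total = multiscale_hub_statistic(p)
        assert total == pytest.approx(
            multiscale_hub_statistic(p[:4]) + multiscale_hub_statistic(p[4:])
        )


class TestHubSignificance:
    def test_uniform_null_no_hubs(self):
        good = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            P = rng.uniform(size=(150, 4))
            _, _, mask = hub_significance(P, 150, seed=seed)
            good += mask.sum() <= 1
        assert good >= 19

    def test_extreme_node_flagged(self, rng):
        P = rng.uniform(0.2, 1.0, size=(100, 4))
        P[7] = np.finfo(float).tiny
        S, corrected, mask = hub_significance(P, 100, seed=0)
        assert mask[7]
        assert S[7] == S.max()

    def test_deterministic(self, rng):
        P = rng.uniform(size=(50, 3))
        a = hub_significance(P, 50, seed=4)
        b = hub_significance(P, 50, seed=4)
        assert np.array_equal(a[2], b[2])


class TestIntersection:
    def test_cases(self):
        assert intersect_multiscale_hubs([{"a", "b"}, {"c"}]) == set()
        assert intersect_multiscale_hubs([{"a", "b"}, {"a", "b"}]) == {"a", "b"}
        assert intersect_multiscale_hubs([{"a", "b", "c"}, {"b", "c", "d"}, {"c"}]) == {"c"}
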