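"""kNN graphs, Leiden communities, specific markers and the merge rule."""

import igraph as ig
import numpy as np
import pytest

from avekit.expression import ExpressionMatrix
from avekit.subclustering import (GRID_KS, GRID_RESOLUTIONS, KnnGraph,
                                  SpecificMarkerRule, community_detect,
                                  count_specific_markers, grid_subcluster,
                                  knn_graph, merge_unsupported,
                                  signature_split)


def _ari(a, b):
    from sklearn.metrics import adjusted_rand_score
    return adjusted_rand_score(a, b)


class TestKnnGraph:
    def test_k_equals_n_minus_one_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        g = knn_graph(rng.normal(0, 1, (12, 6)), n_pcs=3, k=11)
        adj = g.adjacency()
        np.fill_diagonal(adj, True)
        assert adj.all()

    def test_no_cross_cloud_edges_between_distant_clouds(self):
        rng = np.random.default_rng(1)
        pts = np.r_[rng.normal(0, 0.2, (20, 5)), rng.normal(50, 0.2, (20, 5))]
        g = knn_graph(pts, n_pcs=3, k=4)
        adj = g.adjacency()
        assert not adj[:20, 20:].any()

    def test_same_seed_reproduces_neighbor_sets(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 1, (40, 30))
        g1 = knn_graph(pts, n_pcs=5, k=6, seed=3)
        g2 = knn_graph(pts, n_pcs=5, k=6, seed=3)
        np.testing.assert_array_equal(g1.neighbors, g2.neighbors)
        np.testing.assert_allclose(g1.pcs, g2.pcs)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            knn_graph(np.zeros((5, 3)), k=5)


class TestCommunityDetect:
    def test_disconnected_cliques_stay_separate(self):
        g = ig.Graph.Full(8) + ig.Graph.Full(8)
        for r in (0.2, 0.5, 1.0):
            lab = community_detect(g, r, seed=0)
            assert len(set(lab)) == 2
            assert len(set(lab[:8])) == 1 and len(set(lab[8:])) == 1

    def test_low_resolution_limit_single_community(self):
        g = ig.Graph.Erdos_Renyi(n=40, p=0.3)  # connected w.h.p.
        g.add_edges([(i, (i + 1) % 40) for i in range(40)])  # force connected
        lab = community_detect(g, 1e-3, seed=0)
        assert len(set(lab)) == 1

    def test_planted_three_block_graph_recovered(self):
        rng = np.random.default_rng(0)
        sizes = [30, 30, 30]
        truth = np.repeat([0, 1, 2], 30)
        edges = []
        for i in range(90):
            for j in range(i + 1, 90):
                p = 0.4 if truth[i] == truth[j] else 0.02
                if rng.random() < p:
                    edges.append((i, j))
        g = ig.Graph(n=90, edges=edges)
        lab = community_detect(g, 1.0, seed=0)
        assert _ari(truth, lab) >= 0.9


class TestSpecificMarkers:
    def _planted(self, lognorm=2.0):
        rng = np.random.default_rng(0)
        vals = np.abs(rng.normal(0.5, 0.2, (90, 30)))
        labels = np.repeat([0, 1, 2], 30)
        for c in range(3):
            vals[labels == c, c * 3:(c + 1) * 3] += lognorm
        m = ExpressionMatrix(vals, [f"c{i}" for i in range(90)],
                             [f"g{j}" for j in range(30)], layer="lognorm")
        return m, labels

    def test_exclusively_expressed_gene_is_specific(self):
        m, labels = self._planted()
        counts, genes = count_specific_markers(m, labels)
        for c in range(3):
            assert counts[c] >= 3
            assert {f"g{j}" for j in range(c * 3, c * 3 + 3)} <= set(genes[c])

    def test_tied_top_clusters_disqualify(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(0.5, 0.1, (90, 5)))
        labels = np.repeat([0, 1, 2], 30)
        vals[labels != 2, 0] += 2.0   # high in clusters 0 AND 1
        m = ExpressionMatrix(vals, [f"c{i}" for i in range(90)],
                             [f"g{j}" for j in range(5)], layer="lognorm")
        _, genes = count_specific_markers(m, labels)
        assert all("g0" not in genes[c] for c in genes)

    def test_single_cluster_yields_empty_result(self):
        m, _ = self._planted()
        counts, genes = count_specific_markers(m, np.zeros(90))
        assert counts == {} and genes == {}


class TestMergeUnsupported:
    def test_supported_partition_unchanged(self):
        rng = np.random.default_rng(0)
        vals = np.abs(rng.normal(0.3, 0.1, (60, 20)))
        labels = np.repeat([0, 1], 30)
        vals[labels == 0, :5] += 2.0
        vals[labels == 1, 5:10] += 2.0
        m = ExpressionMatrix(vals, [f"c{i}" for i in range(60)],
                             [f"g{j}" for j in range(20)], layer="lognorm")
        pcs = np.column_stack([labels, np.zeros(60)]).astype(float)
        merged, counts = merge_unsupported(m, labels, pcs)
        assert _ari(labels, merged) == 1.0
        assert all(v >= 2 for v in counts.values())

    def test_unsupported_cluster_merges_into_nearest(self):
        rng = np.random.default_rng(1)
        vals = np.abs(rng.normal(0.3, 0.1, (90, 20)))
        labels = np.repeat([0, 1, 2], 30)
        vals[labels == 0, :5] += 2.0            # cluster 0 supported
        vals[np.isin(labels, [1, 2]), 5:10] += 2.0  # 1 and 2 share markers
        m = ExpressionMatrix(vals, [f"c{i}" for i in range(90)],
                             [f"g{j}" for j in range(20)], layer="lognorm")
        # centroids: cluster 2 nearest to cluster 1
        pcs = np.zeros((90, 2))
        pcs[labels == 0, 0] = 10
        pcs[labels == 2, 0] = 1
        merged, counts = merge_unsupported(m, labels, pcs)
        assert len(set(merged)) == 2
        assert set(merged[labels == 1]) == set(merged[labels == 2])

    def test_terminates_on_pure_noise(self):
        rng = np.random.default_rng(2)
        vals = np.abs(rng.normal(0.5, 0.2, (80, 25)))
        labels = rng.integers(0, 4, 80)
        m = ExpressionMatrix(vals, [f"c{i}" for i in range(80)],
                             [f"g{j}" for j in range(25)], layer="lognorm")
        merged, counts = merge_unsupported(m, labels, rng.normal(0, 1, (80, 2)))
        assert len(set(merged)) >= 1  # reached a fixed point


class TestGridSubcluster:
    def test_grid_covers_fifty_points(self, three_cluster_data):
        assert len(GRID_KS) * len(GRID_RESOLUTIONS) == 50

    def test_planted_split_recovered_and_homogeneous_stays_single(self):
        from avekit.simulate import ExpressionSimSpec, simulate_counts
        from avekit.expression import normalize_log, select_hvgs

        spec = ExpressionSimSpec(
            n_cells_per_cluster=[100, 100], n_genes=2000,
            n_marker_genes_per_cluster=0, seed=0,
            marker_blocks=[((1,), tuple(range(300, 310)), -3.0),
                           ((0,), tuple(range(340, 350)), -3.0)])
        m, truth = simulate_counts(spec)
        mn = normalize_log(m, method="library")
        hv = select_hvgs(mn, n_top=300)
        res = grid_subcluster(mn, hv, n_subsamples=8, seed=0)
        assert res.grid.shape[0] == 50
        assert _ari(truth["cluster_labels"], res.selected_partition) >= 0.9
        counts = res.marker_counts[res.selected]
        assert all(v >= 2 for v in counts.values())

        spec0 = ExpressionSimSpec(n_cells_per_cluster=[200], n_genes=2000,
                                  n_marker_genes_per_cluster=0, seed=0)
        m0, _ = simulate_counts(spec0)
        mn0 = normalize_log(m0, method="library")
        res0 = grid_subcluster(mn0, select_hvgs(mn0, n_top=300),
                               n_subsamples=8, seed=0)
        assert len(set(res0.selected_partition)) == 1


class TestSignatureSplit:
    def test_constant_signature_single_cluster(self, lognorm_matrix):
        m = lognorm_matrix(np.ones((40, 6)))
        lab = signature_split(m, [f"g{j}" for j in range(6)], k=5)
        assert len(set(lab)) == 1

    def test_empty_signature_rejected(self, lognorm_matrix):
        m = lognorm_matrix(np.ones((10, 3)))
        with pytest.raises(ValueError):
            signature_split(m, [])

    def test_signature_recovers_weak_planted_split(self):
        """Mirrors the supervised stage split: a 20-gene signature from a
        strong-split dataset separates groups that the marker genes define."""
        rng = np.random.default_rng(0)
        n = 120
        labels = np.repeat([0, 1], 60)
        vals = np.abs(rng.normal(0.5, 0.3, (n, 200)))
        sig_idx = list(range(10)) + list(range(100, 110))
        vals[labels == 0, 0:10] += 1.2
        vals[labels == 1, 100:110] += 1.2
        m = ExpressionMatrix(vals, [f"c{i}" for i in range(n)],
                             [f"g{j}" for j in range(200)], layer="lognorm")
        sig = [f"g{j}" for j in sig_idx]
        lab = signature_split(m, sig, k=15, seed=0)
        assert _ari(labels, lab) >= 0.9
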