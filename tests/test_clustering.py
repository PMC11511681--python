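"""Spearman distance, VI, hybrid tree cut, PAM, outliers and markers."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from avekit.clustering import (MarkerTable, choose_deepsplit_by_kick,
                               knn_outliers, pam_split, rank_markers,
                               ranksum_test, spearman_distance,
                               variation_of_information)
from avekit.expression import ExpressionMatrix


class TestSpearmanDistance:
    def test_self_distance_zero(self):
        d = spearman_distance(np.array([[1., 2, 3], [3, 1, 2]]))
        assert d[0, 0] == 0.0 and d[1, 1] == 0.0

    def test_reversed_ranks_give_one(self):
        d = spearman_distance(np.array([[1., 2, 3, 4], [4, 3, 2, 1]]))
        assert d[0, 1] == pytest.approx(1.0)

    def test_three_cell_toy_with_midranks(self):
        """rho computed by hand with midranks: rows (1,2,3) and (1,3,2)
        have rho = 0.5, hence d = 0.25."""
        d = spearman_distance(np.array([[1., 2, 3], [1, 3, 2], [2, 1, 3]]))
        assert d[0, 1] == pytest.approx(0.25, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(2, (6, 40)).astype(float)
        d = spearman_distance(vals)
        for i, j in itertools.combinations(range(6), 2):
            rho = stats.spearmanr(vals[i], vals[j]).statistic
            assert d[i, j] == pytest.approx((1 - rho) / 2, abs=1e-12)

    def test_constant_cell_gets_neutral_distance(self):
        vals = np.array([[1., 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]])
        d = spearman_distance(vals)
        assert d[0, 1] == 0.5 and d[0, 2] == 0.5 and d[0, 0] == 0.0


def _vi_bruteforce(p1, p2):
    """Independent entropy-based oracle."""
    n = len(p1)
    h1 = h2 = h12 = 0.0
    for c in set(p1):
        q = np.mean(p1 == c)
        h1 -= q * np.log(q)
    for c in set(p2):
        q = np.mean(p2 == c)
        h2 -= q * np.log(q)
    for c1 in set(p1):
        for c2 in set(p2):
            q = np.mean((p1 == c1) & (p2 == c2))
            if q > 0:
                h12 -= q * np.log(q)
    return 2 * h12 - h1 - h2


class TestVariationOfInformation:
    def test_identical_partitions_zero(self):
        p = np.array([0, 0, 1, 1, 2])
        assert variation_of_information(p, p) == 0.0

    def test_crossed_partitions_equal_two_ln_two(self):
        """{ab|cd} vs {ac|bd}: joint entropy ln 4, zero mutual
        information, hence VI = 2 ln 2."""
        vi = variation_of_information([0, 0, 1, 1], [0, 1, 0, 1])
        assert vi == pytest.approx(2 * np.log(2), abs=1e-12)

    def test_one_cluster_vs_singletons(self):
        vi = variation_of_information([0, 0, 0, 0], [0, 1, 2, 3])
        assert vi == pytest.approx(np.log(4), abs=1e-12)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            variation_of_information([0, 1], [0, 1, 2])

    @given(st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_metric_axioms_against_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 12)
        p1, p2, p3 = (rng.integers(0, 3, n) for _ in range(3))
        d12 = variation_of_information(p1, p2)
        assert d12 == pytest.approx(_vi_bruteforce(p1, p2), abs=1e-10)
        assert d12 >= 0
        assert d12 == pytest.approx(variation_of_information(p2, p1))
        d13 = variation_of_information(p1, p3)
        d23 = variation_of_information(p2, p3)
        assert d13 <= d12 + d23 + 1e-10


class TestKickRule:
    def test_flat_curve_falls_back_to_smallest(self):
        assert choose_deepsplit_by_kick({d: 0.7 for d in range(5)}) == 0

    def test_plateau_then_jump(self):
        vi = {0: 0.01, 1: 0.05, 2: 1.2, 3: 1.5, 4: 1.9}
        assert choose_deepsplit_by_kick(vi) == 1

    def test_immediate_jump_keeps_first(self):
        vi = {0: 0.01, 1: 1.4, 2: 1.5, 3: 1.6, 4: 1.7}
        assert choose_deepsplit_by_kick(vi) == 0


class TestPamSplit:
    def _two_clouds(self):
        rng = np.random.default_rng(0)
        pts = np.r_[rng.normal(0, 0.1, (5, 2)), rng.normal(10, 0.1, (5, 2))]
        from scipy.spatial.distance import cdist
        return cdist(pts, pts)

    def test_recovers_separated_groups_vs_bruteforce(self):
        d = self._two_clouds()
        lab = pam_split(d, k=2)
        assert len(set(lab[:5])) == 1 and len(set(lab[5:])) == 1
        assert lab[0] != lab[5]
        # brute-force optimal medoid pair gives the same assignment cost
        best = min(d[:, [i, j]].min(axis=1).sum()
                   for i in range(10) for j in range(i + 1, 10))
        cost = 0.0
        for c in set(lab):
            members = np.flatnonzero(lab == c)
            cost += min(d[np.ix_(members, [m])].sum() for m in members)
        assert cost == pytest.approx(best)

    def test_k_one_returns_distance_sum_minimizer(self):
        d = self._two_clouds()
        lab = pam_split(d, k=1)
        assert len(set(lab)) == 1

    def test_duplicated_cells_stay_together(self):
        pts = np.array([[0.0], [0.0], [5.0], [5.0]])
        from scipy.spatial.distance import cdist
        lab = pam_split(cdist(pts, pts), k=2)
        assert lab[0] == lab[1] and lab[2] == lab[3] and lab[0] != lab[2]


class TestKnnOutliers:
    def test_far_point_flagged(self):
        rng = np.random.default_rng(0)
        pts = np.r_[rng.normal(0, 0.2, (20, 3)), [[8, 8, 8]]]
        flags = knn_outliers(pts, k=3, contamination=1 / 21)
        assert flags[-1] and flags.sum() == 1
        # brute-force: the far point has the largest 3rd-NN distance
        from scipy.spatial.distance import cdist
        d = np.sort(cdist(pts, pts), axis=1)[:, 3]
        assert np.argmax(d) == 20

    def test_zero_contamination_flags_nothing(self):
        rng = np.random.default_rng(1)
        assert not knn_outliers(rng.normal(0, 1, (15, 2)), k=2,
                                contamination=0.0).any()

    def test_identical_points_tie_broken_by_index(self):
        pts = np.zeros((10, 2))
        flags = knn_outliers(pts, k=2, contamination=0.2)
        assert flags.sum() == 2 and flags[0] and flags[1]


class TestRanksumAndMarkers:
    def test_matches_exact_permutation_oracle(self):
        """For tie-free groups of 6 vs 6 the p-value equals the full
        permutation distribution of the rank-sum statistic."""
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 6)
        b = rng.normal(1, 1, 6)
        p = ranksum_test(a[:, None], b[:, None])[0]
        pooled = np.r_[a, b]
        ranks = stats.rankdata(pooled)
        obs = ranks[:6].sum()
        null = [sum(combo) for combo in
                itertools.combinations(ranks, 6)]
        null = np.asarray(null)
        mean = null.mean()
        p_exact = np.mean(np.abs(null - mean) >= abs(obs - mean) - 1e-12)
        assert p == pytest.approx(p_exact, abs=1e-9)

    def test_planted_markers_recovered(self, three_cluster_data):
        mn, truth, hvgs = three_cluster_data
        table = rank_markers(mn, truth["cluster_labels"])
        assert isinstance(table, MarkerTable)
        for c, idx in truth["markers"].items():
            planted = {f"gene{j:05d}" for j in idx}
            top50 = set(table.markers[c][:100])
            recovered = len(planted & set(table.markers[c]))
            assert recovered / len(planted) >= 0.9

    def test_flat_gene_not_selected(self, lognorm_matrix):
        rng = np.random.default_rng(0)
        vals = rng.normal(1, 0.2, (60, 5)).clip(0)
        m = lognorm_matrix(vals)
        table = rank_markers(m, np.r_[np.zeros(30), np.ones(30)])
        assert all("g0" not in v for v in table.markers.values())

    def test_small_fold_change_excluded_despite_tiny_p(self, lognorm_matrix):
        rng = np.random.default_rng(1)
        vals = rng.normal(1, 0.01, (100, 3))
        vals[:50, 0] = np.log(np.expm1(1.0) * 1.4 + 1)  # log2FC ~ 0.49
        m = lognorm_matrix(vals.clip(0))
        labels = np.r_[np.zeros(50), np.ones(50)]
        table = rank_markers(m, labels)
        df = table.pairwise[(0.0, 1.0)]
        assert df.loc["g0", "adj_p"] < 1e-6       # hugely significant
        assert 0 < df.loc["g0", "log2fc"] < 1     # but below the threshold
        assert "g0" not in table.markers[0.0]
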