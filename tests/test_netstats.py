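"""Node statistics: entropy, thresholding, belonging, degree, similarity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from overnet import (
    BinaryGraph,
    CorrelationMatrix,
    MembershipMatrix,
    BelongingConfig,
    belonging_matrix,
    degree_stats,
    disjointify,
    membership_distribution,
    membership_tiers,
    network_cosine_similarity,
    node_entropy,
    participation_coefficient,
    percentile_map,
    threshold_memberships,
)


class TestEntropy:
    def test_one_hot_is_zero_and_uniform_is_one(self):
        assert node_entropy([1, 0, 0, 0, 0, 0, 0]) == 0.0
        assert node_entropy(np.full(7, 1 / 7)) == pytest.approx(1.0)

    def test_two_way_split_hits_log_k_of_two(self):
        # (0.5, 0.5, 0, ..., 0) with K = 7: h = log_7(2) ~ 0.356, the
        # secondary mode of the entropy distribution
        h = node_entropy([0.5, 0.5, 0, 0, 0, 0, 0], K=7)
        assert h == pytest.approx(np.log(2) / np.log(7))
        assert round(h, 2) == 0.36

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(2, 10), st.integers(0, 10_000))
    def test_bounds_hold_on_random_simplices(self, k, seed):
        row = np.random.default_rng(seed).dirichlet(np.ones(k))
        h = node_entropy(row, k)
        assert 0.0 <= h <= 1.0 + 1e-12


class TestThresholdMemberships:
    def test_constant_positive_kept_and_zero_zeroed(self):
        runs = [
            MembershipMatrix(np.array([[0.5, 0.5, 0.0]] * 2)) for _ in range(4)
        ]
        out = threshold_memberships(runs)
        assert np.allclose(out.pi[:, :2], 0.5)
        assert (out.pi[:, 2] == 0).all()

    def test_matches_brute_force_t_and_bh(self, rng):
        from scipy import stats as sp

        vals = rng.dirichlet(np.ones(3), size=(4, 5))  # 4 runs, 5 nodes
        runs = [MembershipMatrix(v) for v in vals]
        out = threshold_memberships(runs, fdr_q=0.05)
        # brute-force: per-entry one-sided t-test, then literal BH step-up
        pvals = np.empty(15)
        for idx, (i, k) in enumerate(
            [(i, k) for i in range(5) for k in range(3)]
        ):
            x = vals[:, i, k]
            t = x.mean() / (x.std(ddof=1) / 2.0)
            pvals[idx] = sp.t.sf(t, df=3)
        order = np.argsort(pvals)
        m = pvals.size
        passed = np.zeros(m, dtype=bool)
        max_rank = 0
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= 0.05 * rank / m:
                max_rank = rank
        passed[order[:max_rank]] = True
        keep = passed.reshape(5, 3)
        mean = vals.mean(axis=0)
        expected = np.where(keep, mean, 0.0)
        sums = expected.sum(axis=1, keepdims=True)
        expected = np.where(sums > 0, expected / np.maximum(sums, 1e-300), 0.0)
        assert np.allclose(out.pi, expected)


class TestBelonging:
    def test_tight_one_hot_belongs_once(self):
        pi = MembershipMatrix(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
        se = np.full((2, 3), 1e-6)
        res = belonging_matrix(pi, se)
        assert res.counts.tolist() == [1, 1]
        assert res.overlap_score == 0.0

    def test_everything_overlapping_scores_one(self):
        # every node clearly above the 1/K null level in two communities
        pi = MembershipMatrix(np.tile([0.45, 0.45, 0.1], (4, 1)))
        se = np.full((4, 3), 1e-6)
        res = belonging_matrix(pi, se)
        assert (res.counts == 2).all()
        assert res.overlap_score == 1.0

    def test_counts_match_hand_computed_thresholds(self):
        # one node comfortably above 1/3 in two communities, one in none
        pi = MembershipMatrix(
            np.array([[0.55, 0.44, 0.01], [0.34, 0.33, 0.33]])
        )
        se = np.array([[0.02, 0.02, 0.02], [0.2, 0.2, 0.2]])
        res = belonging_matrix(pi, se, BelongingConfig(alpha_level=0.05))
        # node 0: t = (0.55-1/3)/.02 ~ 10.8 and (0.44-1/3)/.02 ~ 5.3 -> both in
        # node 1: t <= 0.035 -> nothing
        assert res.counts.tolist() == [2, 0]

    def test_tiers_rank_by_exceeded_multiple(self):
        pi = MembershipMatrix(np.array([[0.9, 0.1], [0.55, 0.45]]))
        se = np.full((2, 2), 0.01)
        tiers = membership_tiers(
            pi, se, tier_multipliers=(0.5, 1.0, 1.5), cfg=BelongingConfig()
        )
        # with 1/K = 0.5: 0.9 > 1.5*0.5=0.75 -> top tier; 0.55 > 0.5 but
        # not > 0.75 -> middle tier; small values -> none
        assert tiers[0, 0] == 3
        assert tiers[1, 0] == 2
        assert tiers[0, 1] == 0


class TestDistributions:
    def test_disjoint_input_concentrates_in_top_bin(self):
        pi = np.full((20, 7), 0.2 / 6)
        pi[:, 0] = 0.8
        pi[:5, 0] = 0.95
        pi[:5, 1:] = 0.05 / 6
        hist, bins = membership_distribution(MembershipMatrix(pi))
        assert hist[-1] >= 80.0

    def test_uniform_memberships_fall_below_floor(self):
        pi = MembershipMatrix(np.full((10, 7), 1 / 7))
        with pytest.warns(RuntimeWarning, match="floor"):
            hist, _ = membership_distribution(pi)
        assert (hist == 0).all()

    def test_hand_built_case_matches_manual_binning(self):
        pi = np.zeros((10, 2))
        pi[:, 0] = [0.95, 0.85, 0.75, 0.65, 0.55, 0.45, 0.35, 0.25, 0.15, 0.05]
        pi[:, 1] = 1 - pi[:, 0]
        hist, _ = membership_distribution(MembershipMatrix(pi))
        # considered values (> 0.2): 8 + 8 = 16, four per bin from each column
        assert np.allclose(hist, [25.0, 25.0, 25.0, 25.0])

    def test_percentile_map_orders_by_t_statistic(self, rng):
        base = np.array([0.0, 1.0, 2.0, 3.0])
        vals = base + 0.1 * rng.standard_normal((6, 4))
        pm = percentile_map(vals)
        assert list(np.argsort(pm)) == [0, 1, 2, 3]
        assert pm.max() == 100.0


class TestDegreeAndParticipation:
    def test_complete_and_edgeless_graphs(self):
        n = 6
        complete = BinaryGraph(np.ones((n, n), dtype=int) - np.eye(n, dtype=int))
        assert (degree_stats(complete)["degree"] == n - 1).all()
        with pytest.warns(RuntimeWarning):
            pc = participation_coefficient(
                BinaryGraph(np.zeros((n, n), dtype=int)), np.zeros(n, dtype=int)
            )
        assert (pc == 0).all()

    def test_degree_matches_adjacency_row_sums(self, rng):
        a = np.triu(rng.random((5, 5)) < 0.5, 1).astype(int)
        g = BinaryGraph(a + a.T)
        stats = degree_stats(g)
        assert np.array_equal(stats["degree"], g.adjacency.sum(axis=0))
        assert np.allclose(stats["normalized_degree"], stats["degree"] / 5)

    def test_weighted_degree_sums_retained_weights(self, rng):
        vals = np.corrcoef(rng.standard_normal((5, 30)))
        corr = CorrelationMatrix(vals)
        a = np.ones((5, 5), dtype=int) - np.eye(5, dtype=int)
        g = BinaryGraph(a)
        wd = degree_stats(g, corr)["weighted_degree"]
        expected = vals.sum(axis=1) - 1.0  # full graph, minus diagonal
        assert np.allclose(wd, expected)

    def test_participation_closed_forms(self):
        # all links within one module -> 0; equal links to K modules -> 1-1/K
        a = np.zeros((9, 9), dtype=int)
        # node 0 connects to one node in each of 3 modules
        for j in (1, 4, 7):
            a[0, j] = a[j, 0] = 1
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 2, 2])
        pc = participation_coefficient(BinaryGraph(a), labels)
        assert pc[0] == pytest.approx(1 - 1 / 3)
        assert pc[1] == 0.0  # its single link stays in its own module

    def test_participation_matches_brute_force_on_small_graphs(self, rng):
        for _ in range(5):
            n = int(rng.integers(5, 30))
            a = np.triu(rng.random((n, n)) < 0.3, 1).astype(int)
            g = BinaryGraph(a + a.T)
            labels = rng.integers(0, 3, n)
            pc = participation_coefficient(g, labels)
            for i in range(n):
                deg = g.adjacency[i].sum()
                if deg == 0:
                    assert pc[i] == 0.0
                    continue
                expected = 1.0
                for m in np.unique(labels):
                    k_im = sum(
                        g.adjacency[i, j] for j in range(n) if labels[j] == m
                    )
                    expected -= (k_im / deg) ** 2
                assert pc[i] == pytest.approx(expected)


class TestSimilarityAndDisjointify:
    def test_anchor_points(self, rng):
        u = rng.standard_normal(30)
        assert network_cosine_similarity(u, u) == pytest.approx(1.0)
        assert network_cosine_similarity(u, -u) == pytest.approx(0.0)
        v = rng.standard_normal(30)
        u0 = u - u.mean()
        v_orth = v - v.mean()
        v_orth -= (v_orth @ u0) / (u0 @ u0) * u0
        assert network_cosine_similarity(u, v_orth + v_orth.mean()) == (
            pytest.approx(0.5, abs=1e-9)
        )

    def test_disjointify_argmax_with_low_index_ties(self):
        pi = MembershipMatrix(
            np.array([[0.6, 0.4, 0.0], [0.5, 0.5, 0.0], [0.1, 0.2, 0.7]])
        )
        with pytest.warns(RuntimeWarning, match="tied"):
            labels = disjointify(pi)
        assert labels.tolist() == [0, 0, 2]
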