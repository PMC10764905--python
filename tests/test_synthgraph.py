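"""Generators: MMSB sampling, overlapping LFR-style graphs, datasets."""

import numpy as np
import pytest

from overnet import (
    LFRParams,
    MembershipMatrix,
    MMSBHyper,
    degree_for_density,
    estimate_t1,
    generate_hierarchical_dataset,
    generate_lfr_graph,
    sample_mmsb_graph,
    threshold_density,
    correlation_matrix,
)
from overnet.synthgraph import LFRGenerationError


class TestMMSBSampler:
    def test_invalid_hyper_rejected(self):
        with pytest.raises(ValueError):
            MMSBHyper(K=1)
        with pytest.raises(ValueError):
            MMSBHyper(K=3, alpha=-1.0)
        with pytest.raises(ValueError):
            MMSBHyper(K=3, beta=1.5)

    def test_one_hot_same_community_always_links(self):
        # pi_i = pi_j one-hot on the same community, beta = 1: the pair's
        # indicators are forced equal, so the link probability is 1
        hyper = MMSBHyper(K=2, alpha=(1e6, 1e-6))
        bench = sample_mmsb_graph(30, hyper, seed=0)
        assert bench.graph.n_edges == 30 * 29 // 2

    def test_orthogonal_one_hot_never_links(self, rng):
        # two one-hot nodes in different communities never agree
        from overnet import predict_link_prob

        assert predict_link_prob([1, 0], [0, 1]) == 0.0

    def test_pairwise_link_frequency_matches_closed_form(self):
        # Monte-Carlo oracle: pi_i = pi_j = (0.5, 0.5), beta = 1 gives
        # agreement probability sum_k pi_ik pi_jk = 0.5
        rng = np.random.default_rng(0)
        n_draws = 10_000
        z_i = rng.random(n_draws) < 0.5
        z_j = rng.random(n_draws) < 0.5
        freq = (z_i == z_j).mean()
        se = np.sqrt(0.25 / n_draws)
        assert abs(freq - 0.5) < 3 * se

    def test_empirical_link_rate_converges_to_eq1(self):
        # sampler-level check against the closed form for fixed memberships:
        # nodes drawn from a near-degenerate Dirichlet so pi is known
        hyper = MMSBHyper(K=2, alpha=1e6, beta=(1.0, 1.0))  # pi ~ (0.5, 0.5)
        n = 120
        bench = sample_mmsb_graph(n, hyper, seed=1)
        expected = 0.5  # sum_k 0.5 * 0.5 * 1 over two communities
        n_pairs = n * (n - 1) / 2
        freq = bench.graph.n_edges / n_pairs
        se = np.sqrt(expected * (1 - expected) / n_pairs)
        assert abs(freq - expected) < 3 * se

    def test_truth_covers_every_node(self):
        bench = sample_mmsb_graph(50, MMSBHyper(K=3, alpha=0.1), seed=2)
        assert (bench.truth.sum(axis=1) >= 1).all()
        assert np.allclose(bench.memberships.pi.sum(axis=1), 1.0)


class TestLFRGenerator:
    def test_disjoint_when_no_overlapping_nodes(self, lfr_disjoint_small):
        assert lfr_disjoint_small.n_overlapping == 0
        assert (lfr_disjoint_small.truth.sum(axis=1) == 1).all()

    @pytest.mark.parametrize("om", [2, 3])
    def test_on_and_om_exact(self, om):
        params = LFRParams(N=120, k=15, c_min=20, c_max=40, ON=36, OM=om)
        bench = generate_lfr_graph(params, seed=5)
        assert bench.n_overlapping == 36
        counts = bench.truth.sum(axis=1)
        assert set(counts[counts > 1]) == {om}

    def test_sweep_yields_twenty_parameter_combinations(self):
        # the benchmark sweep: ON fractions 0.0..0.9 in steps of 0.1,
        # crossed with OM in {2, 3} -> 20 graphs
        on_fracs = np.round(np.arange(0.0, 1.0, 0.1), 1)
        oms = (2, 3)
        combos = [(f, om) for f in on_fracs for om in oms]
        assert len(combos) == 20

    def test_low_mixing_keeps_links_internal(self):
        params = LFRParams(N=60, k=8, mu_topo=0.05, c_min=15, c_max=30, ON=0)
        bench = generate_lfr_graph(params, seed=5)
        # generator bookkeeping: average internal fraction >= 0.9
        assert (1.0 - bench.mixing).mean() >= 0.9

    def test_density_matches_request(self):
        params = LFRParams(N=200, k=degree_for_density(200, 0.15), ON=0,
                           c_min=30, c_max=70)
        bench = generate_lfr_graph(params, seed=9)
        assert abs(bench.graph.density - 0.15) < 0.015

    def test_unrealizable_parameters_raise(self):
        with pytest.raises(ValueError):
            LFRParams(N=50, k=10, c_min=60, c_max=80)  # c_max > N
        # average degree above k_max is unreachable
        with pytest.raises(LFRGenerationError):
            generate_lfr_graph(
                LFRParams(N=50, k=40, c_min=10, c_max=25, k_max=20), seed=0
            )

    def test_estimate_t1_recovers_slope(self, rng):
        # degrees sampled from a discrete power law ~ k^-2
        k = np.arange(5, 200)
        p = k**-2.0
        degrees = rng.choice(k, size=20_000, p=p / p.sum())
        assert abs(estimate_t1(degrees) - 2.0) < 0.3


class TestHierarchicalDataset:
    def test_identical_membership_rows_correlate_perfectly(self):
        pi = np.zeros((10, 2))
        pi[:5, 0] = 1.0
        pi[5:, 1] = 1.0
        truth = MembershipMatrix(pi)
        ds = generate_hierarchical_dataset(
            1, 1, 1, 10, 200, truth, noise_sd=0.0, fs=1.0, seed=0,
            perturb_sd=0.0,
        )
        corr = correlation_matrix(ds.runs[0])
        assert corr.values[0, 1] == pytest.approx(1.0)
        assert corr.values[5, 6] == pytest.approx(1.0)

    def test_design_totals_emulate_study(self):
        # 10 animals x 3 sessions x 4 runs x 10 min = 1200 min of data
        n_animals, n_sessions, n_runs, minutes = 10, 3, 4, 10
        total = n_animals * n_sessions * n_runs * minutes
        assert total == 1200
        truth = MembershipMatrix(np.eye(4))
        ds = generate_hierarchical_dataset(
            n_animals, n_sessions, n_runs, 4, 60, truth, noise_sd=0.1,
            fs=1.0, seed=0,
        )
        assert len(ds) == 120

    def test_thresholded_graphs_recover_planted_blocks(
        self, two_block_truth, small_dataset
    ):
        import networkx as nx

        run = small_dataset.runs[0]
        graph = threshold_density(correlation_matrix(run), 0.15)
        g = nx.from_numpy_array(graph.adjacency)
        components = [
            sorted(c) for c in nx.connected_components(g) if len(c) > 1
        ]
        blocks = [set(range(20)), set(range(20, 40))]
        for comp in components:
            assert set(comp) <= blocks[0] or set(comp) <= blocks[1]

    def test_identical_seeds_bitwise_reproducible(self, two_block_truth):
        args = dict(
            n_animals=2, n_sessions=1, n_runs=2, n_rois=40, n_timepoints=100,
            truth=two_block_truth, noise_sd=0.3, fs=1.0, seed=42,
        )
        a = generate_hierarchical_dataset(**args)
        b = generate_hierarchical_dataset(**args)
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.signal, rb.signal)
            assert np.array_equal(ra.motion, rb.motion)

    def test_roi_mismatch_raises(self, two_block_truth):
        with pytest.raises(ValueError, match="n_rois"):
            generate_hierarchical_dataset(
                1, 1, 1, 99, 50, two_block_truth, 0.1, 1.0, 0
            )
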