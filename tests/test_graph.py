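import numpy as np
import pytest

from restdyn._louvain import louvain_signed, modularity_signed
from restdyn.dynamics import CouplingTensor
from restdyn.evaluation import (
    exhaustive_best_partition,
    module_zscore_bruteforce,
    participation_bruteforce,
    two_clique_graph,
)
from restdyn.graph import (
    INTEGRATED,
    SEGREGATED,
    CartographyTrace,
    CommunityTrajectory,
    classify_states,
    node_cartography,
    state_statistics,
    subject_graph_summary,
    time_resolved_partition,
)
from restdyn.io import ValidationError


def tensor_from_slices(slices):
    slices = np.asarray(slices, dtype=float)
    if slices.ndim == 2:
        slices = slices[None]
    vals = np.moveaxis(slices, 0, 2)
    return CouplingTensor(
        values=vals,
        window_length=1,
        tr_seconds=1.0,
        region_labels=[f"r{i}" for i in range(vals.shape[0])],
    )


class TestLouvain:
    def test_two_cliques_recovered_with_half_modularity(self):
        W = two_clique_graph()
        traj = time_resolved_partition(tensor_from_slices(W), seed=0)
        labels = traj.partitions[:, 0]
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:3])) == 1 and len(np.unique(labels[3:])) == 1
        assert traj.q_trace[0] == pytest.approx(0.5, abs=1e-12)
        _, q_star = exhaustive_best_partition(W)
        assert traj.q_trace[0] == pytest.approx(q_star, abs=1e-12)

    def test_never_exceeds_exhaustive_optimum_on_random_graphs(self, rng):
        for _ in range(10):
            a = rng.normal(size=(6, 6))
            W = (a + a.T) / 2
            np.fill_diagonal(W, 0.0)
            _, q_star = exhaustive_best_partition(W)
            q = max(
                modularity_signed(W, louvain_signed(W, rng=rng)) for _ in range(5)
            )
            assert q <= q_star + 1e-9

    def test_uniform_complete_graph_near_degenerate(self):
        W = np.ones((6, 6))
        np.fill_diagonal(W, 0.0)
        traj = time_resolved_partition(tensor_from_slices(W), seed=0)
        assert traj.q_trace[0] <= 0.05

    def test_all_zero_slice_flagged_singletons(self):
        traj = time_resolved_partition(tensor_from_slices(np.zeros((5, 5))), seed=0)
        assert traj.degenerate_windows == [0]
        assert traj.q_trace[0] == 0.0
        assert len(np.unique(traj.partitions[:, 0])) == 5

    def test_planted_two_block_tensor_recovered_at_every_index(self, rng):
        n = 12
        W = np.full((n, n), 0.05)
        W[:6, :6] = 0.8
        W[6:, 6:] = 0.8
        np.fill_diagonal(W, 0.0)
        slices = [W + 0.01 * rng.standard_normal((n, n)) for _ in range(5)]
        slices = [(s + s.T) / 2 for s in slices]
        traj = time_resolved_partition(tensor_from_slices(slices), seed=1)
        planted = np.repeat([0, 1], 6)
        for t in range(5):
            labels = traj.partitions[:, t]
            # adjusted Rand index 1 <=> identical up to relabelling
            assert len(np.unique(labels)) == 2
            assert all(
                len(np.unique(labels[planted == b])) == 1 for b in (0, 1)
            )


class TestCartography:
    def test_all_within_module_coupling_gives_zero_participation(self):
        W = two_clique_graph()
        traj = time_resolved_partition(tensor_from_slices(W), seed=0)
        cart = node_cartography(tensor_from_slices(W), traj)
        np.testing.assert_allclose(cart.B[:, 0], 0.0, atol=1e-12)

    def test_even_split_participation_half(self):
        # node 0 couples 2 units into each of two modules -> B = 0.5
        W = np.zeros((5, 5))
        W[0, 1] = W[0, 2] = 1.0  # module of nodes 1,2 (with 0)
        W[0, 3] = W[0, 4] = 1.0
        W = W + W.T
        W[1, 2] = W[2, 1] = 1.0
        W[3, 4] = W[4, 3] = 1.0
        labels = np.array([0, 0, 0, 1, 1])
        traj = CommunityTrajectory(
            partitions=labels[:, None], q_trace=np.zeros(1), gamma=1.0, louvain_seed=0
        )
        cart = node_cartography(tensor_from_slices(W), traj)
        assert cart.B[0, 0] == pytest.approx(0.5)

    def test_matches_bruteforce_on_random_toy_graphs(self, rng):
        for _ in range(10):
            a = rng.normal(size=(10, 10))
            W = (a + a.T) / 2
            np.fill_diagonal(W, 0.0)
            labels = rng.integers(0, 3, size=10)
            traj = CommunityTrajectory(
                partitions=labels[:, None], q_trace=np.zeros(1),
                gamma=1.0, louvain_seed=0,
            )
            cart = node_cartography(tensor_from_slices(W), traj)
            np.testing.assert_allclose(
                cart.B[:, 0], participation_bruteforce(W, labels), atol=1e-12
            )
            np.testing.assert_allclose(
                cart.W[:, 0], module_zscore_bruteforce(W, labels), atol=1e-9
            )
            assert (cart.B[:, 0] >= 0).all() and (cart.B[:, 0] <= 1).all()

    def test_uniform_module_strengths_give_zero_zscores(self):
        W = two_clique_graph()
        labels = np.repeat([0, 1], 3)
        traj = CommunityTrajectory(
            partitions=labels[:, None], q_trace=np.zeros(1), gamma=1.0, louvain_seed=0
        )
        cart = node_cartography(tensor_from_slices(W), traj)
        np.testing.assert_allclose(cart.W[:, 0], 0.0, atol=1e-12)

    def test_module_mean_zscore_is_zero(self, rng):
        a = rng.normal(size=(12, 12))
        W = (a + a.T) / 2
        np.fill_diagonal(W, 0.0)
        labels = rng.integers(0, 3, size=12)
        traj = CommunityTrajectory(
            partitions=labels[:, None], q_trace=np.zeros(1), gamma=1.0, louvain_seed=0
        )
        cart = node_cartography(tensor_from_slices(W), traj)
        for module in np.unique(labels):
            assert cart.W[labels == module, 0].mean() == pytest.approx(0.0, abs=1e-9)

    def test_zero_strength_node_flagged(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 1.0
        labels = np.array([0, 0, 1, 1])
        traj = CommunityTrajectory(
            partitions=labels[:, None], q_trace=np.zeros(1), gamma=1.0, louvain_seed=0
        )
        cart = node_cartography(tensor_from_slices(W), traj)
        assert cart.B[2, 0] == 0.0
        assert (2, 0) in cart.zero_strength_flags


def make_cartography(mean_b, mean_w=None, n_nodes=4):
    """Build a trace whose node-mean features equal the given sequences."""
    mean_b = np.asarray(mean_b, dtype=float)
    if mean_w is None:
        mean_w = np.zeros_like(mean_b)
    B = np.tile(mean_b, (n_nodes, 1))
    W = np.tile(np.asarray(mean_w, dtype=float), (n_nodes, 1))
    return CartographyTrace(B=B, W=W)


class TestStateClassification:
    def test_two_pure_clusters_t4(self):
        cart = make_cartography([1.0, 1.0, 0.0, 0.0], [0.0, 0.0, 1.0, 1.0])
        states = classify_states(cart, seed=0)
        assert list(states.labels) == [INTEGRATED, INTEGRATED, SEGREGATED, SEGREGATED]
        assert states.centroids[INTEGRATED][0] > states.centroids[SEGREGATED][0]

    def test_tie_on_mean_b_breaks_to_lower_mean_w(self):
        cart = make_cartography([0.5, 0.5, 0.5, 0.5], [1.0, 1.0, 0.0, 0.0])
        states = classify_states(cart, seed=0)
        assert states.tie_broken
        # lower mean-W cluster labelled integrated by the tie-break contract
        assert list(states.labels) == [SEGREGATED, SEGREGATED, INTEGRATED, INTEGRATED]

    def test_well_separated_features_recovered(self, rng):
        truth = rng.random(60) < 0.5
        mean_b = np.where(truth, 0.8, 0.2) + 0.02 * rng.standard_normal(60)
        cart = make_cartography(mean_b)
        states = classify_states(cart, seed=0)
        agreement = (states.labels == np.where(truth, INTEGRATED, SEGREGATED)).mean()
        assert agreement >= 0.95

    def test_degenerate_features_rejected(self):
        cart = make_cartography([0.5] * 6, [0.1] * 6)
        with pytest.raises(ValidationError, match="variance"):
            classify_states(cart, seed=0)


class TestCohortStateClassification:
    def test_single_state_subject_handled_by_pooled_clustering(self, rng):
        from restdyn.graph import classify_states_cohort

        mixed = make_cartography(
            np.r_[np.full(30, 0.8), np.full(30, 0.2)]
            + 0.02 * rng.standard_normal(60)
        )
        stuck = make_cartography(np.full(40, 0.2) + 0.02 * rng.standard_normal(40))
        seqs = classify_states_cohort([mixed, stuck], seed=0)
        assert (seqs[1].labels == SEGREGATED).mean() >= 0.95
        assert (seqs[0].labels[:30] == INTEGRATED).mean() >= 0.95
        # shared centroids across the cohort
        assert seqs[0].centroids == seqs[1].centroids

    def test_mode_filter_removes_subwindow_flickers(self, rng):
        truth = np.r_[np.zeros(50), np.ones(50)].astype(int)
        mean_b = np.where(truth == 1, 0.8, 0.2).astype(float)
        flip = [10, 25, 70, 90]
        mean_b[flip] = np.where(truth[flip] == 1, 0.2, 0.8)  # isolated errors
        cart = make_cartography(mean_b)
        noisy = classify_states(cart, seed=0)
        smoothed = classify_states(cart, seed=0, smooth_window=15)
        expected = np.where(truth == 1, INTEGRATED, SEGREGATED)
        assert (noisy.labels != expected).sum() == 4
        assert (smoothed.labels == expected).all()


class TestStateStatistics:
    def _seq(self, labels):
        return type(
            "S", (), {"labels": np.array(labels)}
        )()

    def test_half_half_sequence(self):
        seq = self._seq([INTEGRATED] * 3 + [SEGREGATED] * 3)
        summary = state_statistics(seq, tr_seconds=2.0)
        assert summary.n_transitions == 1
        assert summary.dwell_windows[INTEGRATED] == 3
        assert summary.dwell_windows[SEGREGATED] == 3
        assert summary.dwell_seconds[INTEGRATED] == 6.0
        assert summary.fraction_time == {INTEGRATED: 0.5, SEGREGATED: 0.5}

    def test_alternating_sequence(self):
        seq = self._seq([INTEGRATED, SEGREGATED, INTEGRATED, SEGREGATED])
        summary = state_statistics(seq, tr_seconds=1.0)
        assert summary.n_transitions == 3
        assert summary.dwell_windows[INTEGRATED] == 1
        assert summary.dwell_windows[SEGREGATED] == 1

    def test_single_state_sequence_flags_absent_state(self):
        seq = self._seq([INTEGRATED] * 5)
        summary = state_statistics(seq, tr_seconds=1.0)
        assert summary.n_transitions == 0
        assert summary.fraction_time[INTEGRATED] == 1.0
        assert np.isnan(summary.dwell_windows[SEGREGATED])
        assert SEGREGATED in summary.undefined_states


def test_summary_invariant_to_region_relabelling(rng):
    # planted two-block slices: the optimal partition is unique, so the
    # summaries must agree exactly across a node relabelling
    base_slice = np.full((10, 10), 0.05)
    base_slice[:5, :5] = 0.7
    base_slice[5:, 5:] = 0.7
    np.fill_diagonal(base_slice, 0.0)
    noise = 0.01 * rng.standard_normal((10, 10, 3))
    vals = base_slice[:, :, None] + (noise + np.swapaxes(noise, 0, 1)) / 2
    tensor = CouplingTensor(vals, 1, 1.0, [f"r{i}" for i in range(10)])
    traj = time_resolved_partition(tensor, seed=0, n_restarts=5)
    cart = node_cartography(tensor, traj)
    base = subject_graph_summary(traj, cart)
    perm = rng.permutation(10)
    tensor_p = CouplingTensor(
        vals[np.ix_(perm, perm)], 1, 1.0, [f"r{i}" for i in perm]
    )
    traj_p = time_resolved_partition(tensor_p, seed=0, n_restarts=5)
    cart_p = node_cartography(tensor_p, traj_p)
    permuted = subject_graph_summary(traj_p, cart_p)
    assert permuted["mean_Q"] == pytest.approx(base["mean_Q"], abs=1e-6)
    assert permuted["mean_B"] == pytest.approx(base["mean_B"], abs=1e-6)
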