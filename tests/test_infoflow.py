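import numpy as np
import pytest

from actiflow.descriptors import FeatureMatrix
from actiflow.infoflow import (
    ContactTrace,
    classify_roles,
    hits_scores,
    residue_state_series,
    te_direct_sum,
    te_matrix,
    transfer_entropy,
    _te_decomposition,
)
from actiflow.synthetic import CoupledContactSpec, simulate_coupled_contacts


def contact_matrix_to_feature(x):
    return FeatureMatrix(blocks=[x.astype(float)], names=[f"c{i}" for i in range(x.shape[1])],
                         frame_interval_ns=1.0)


class TestResidueStateSeries:
    def test_single_column_alphabet_binary(self):
        x = np.array([[0], [1], [1], [0]])
        trace = residue_state_series(contact_matrix_to_feature(x), {"r1": [0]})
        assert trace.alphabet_size("r1") == 2

    def test_three_columns_full_alphabet(self):
        combos = np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).T.reshape(-1, 3)
        trace = residue_state_series(contact_matrix_to_feature(combos), {"r": [0, 1, 2]})
        assert trace.alphabet_size("r") == 8

    def test_constant_columns_collapse_to_one_symbol(self):
        x = np.ones((50, 2))
        trace = residue_state_series(contact_matrix_to_feature(x), {"r": [0, 1]})
        assert trace.alphabet_size("r") == 1

    def test_non_binary_rejected(self):
        x = np.full((10, 1), 2.0)
        with pytest.raises(ValueError, match="binary"):
            residue_state_series(contact_matrix_to_feature(x), {"r": [0]})


class TestTransferEntropy:
    def test_independent_processes_near_zero(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 2, 100_000)
        y = rng.integers(0, 2, 100_000)
        assert abs(transfer_entropy(x, y, seed=1)) < 0.01

    def test_lag_one_copy_carries_one_bit(self):
        spec = CoupledContactSpec(2, {1: 0}, lag=1, noise=0.0, n_frames=100_000, seed=2)
        x = simulate_coupled_contacts(spec)
        forward = transfer_entropy(x[:, 0], x[:, 1], seed=3)
        backward = transfer_entropy(x[:, 1], x[:, 0], seed=4)
        assert forward == pytest.approx(1.0, abs=0.01)
        assert abs(backward) < 0.01

    def test_decomposition_equals_direct_summation_exactly(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.integers(0, 3, 500)
            b = rng.integers(0, 2, 500)
            c = rng.integers(0, 4, 500)
            assert _te_decomposition(a, b, c) == pytest.approx(te_direct_sum(a, b, c), abs=1e-12)

    def test_raw_te_is_non_negative(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            tgt = rng.integers(0, 2, 300)
            src = rng.integers(0, 2, 300)
            raw = _te_decomposition(tgt[1:], tgt[:-1], src[:-1])
            assert raw >= -1e-12

    def test_corrected_te_concentrates_near_zero_over_seeds(self):
        values = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 2, 20_000)
            y = rng.integers(0, 2, 20_000)
            values.append(transfer_entropy(x, y, seed=seed + 100))
        assert np.max(np.abs(values)) < 0.01


class TestTeMatrix:
    def make_trace(self, n_traj=5, n_frames=20_000, noise=0.0, seed=7):
        blocks = []
        for i in range(n_traj):
            spec = CoupledContactSpec(3, {1: 0}, lag=1, noise=noise,
                                      n_frames=n_frames, seed=seed + i)
            blocks.append(simulate_coupled_contacts(spec).astype(np.int64))
        return ContactTrace(nodes=["driver", "follower", "bystander"], blocks=blocks)

    def test_full_fraction_single_repeat_equals_direct_computation(self):
        trace = self.make_trace(n_traj=2, n_frames=5_000)
        m = te_matrix(trace, subsample_fraction=1.0, n_repeats=1, seed=8)
        j, i = trace.nodes.index("driver"), trace.nodes.index("follower")
        direct = transfer_entropy([b[:, 0] for b in trace.blocks],
                                  [b[:, 1] for b in trace.blocks], seed=0)
        assert m.values[j, i] == pytest.approx(direct, abs=0.02)

    def test_planted_coupling_detected_directionally(self):
        trace = self.make_trace()
        m = te_matrix(trace, subsample_fraction=0.6, n_repeats=3, seed=9)
        d, f = trace.nodes.index("driver"), trace.nodes.index("follower")
        assert m.values[d, f] > 0.9
        assert abs(m.values[f, d]) < 0.05

    def test_deterministic_given_seed(self):
        trace = self.make_trace(n_traj=3, n_frames=2_000)
        a = te_matrix(trace, subsample_fraction=0.5, n_repeats=2, seed=10)
        b = te_matrix(trace, subsample_fraction=0.5, n_repeats=2, seed=10)
        np.testing.assert_array_equal(a.values, b.values)


class TestHits:
    def test_symmetric_complete_graph_all_equal(self):
        n = 4
        A = np.ones((n, n)) - np.eye(n)
        s = hits_scores(A)
        np.testing.assert_allclose(s.authority, 1.0, atol=1e-10)
        np.testing.assert_allclose(s.hub, 1.0, atol=1e-10)

    def test_two_sources_one_sink(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[2, 1] = 1.0
        s = hits_scores(A)
        assert s.authority[1] == pytest.approx(1.0)
        assert s.authority[0] == pytest.approx(0.0, abs=1e-10)
        assert s.hub[0] == pytest.approx(s.hub[2], abs=1e-10) == pytest.approx(1.0)

    def test_matches_brute_force_eigenvectors_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            A = rng.uniform(0, 1, (5, 5))
            np.fill_diagonal(A, 0.0)
            s = hits_scores(A)
            _, va = np.linalg.eigh(A.T @ A)
            _, vh = np.linalg.eigh(A @ A.T)
            a_ref = np.abs(va[:, -1])
            h_ref = np.abs(vh[:, -1])
            np.testing.assert_allclose(s.authority, a_ref / a_ref.max(), atol=1e-8)
            np.testing.assert_allclose(s.hub, h_ref / h_ref.max(), atol=1e-8)

    def test_invariant_to_uniform_edge_rescaling(self):
        rng = np.random.default_rng(12)
        A = rng.uniform(0, 1, (6, 6))
        np.fill_diagonal(A, 0.0)
        s1 = hits_scores(A)
        s2 = hits_scores(A * 37.5)
        np.testing.assert_allclose(s1.authority, s2.authority, atol=1e-10)
        np.testing.assert_allclose(s1.hub, s2.hub, atol=1e-10)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="positive edges"):
            hits_scores(np.zeros((3, 3)))


class TestClassifyRoles:
    def test_pure_transmitter_receiver_connector(self):
        from actiflow.infoflow import NodeScores

        scores = NodeScores(nodes=["t", "r", "c", "n"],
                            authority=np.array([0.0, 1.0, 1.0, 0.1]),
                            hub=np.array([1.0, 0.0, 1.0, 0.1]))
        roles = classify_roles(scores, 0.5, 0.5)
        assert list(roles["role"]) == ["transmitter", "receiver", "connector", "none"]

    def test_planted_driver_follower_roles(self):
        blocks = []
        for i in range(3):
            spec = CoupledContactSpec(2, {1: 0}, lag=1, noise=0.0, n_frames=20_000, seed=20 + i)
            blocks.append(simulate_coupled_contacts(spec).astype(np.int64))
        trace = ContactTrace(nodes=["driver", "follower"], blocks=blocks)
        m = te_matrix(trace, subsample_fraction=1.0, n_repeats=1, seed=21)
        roles = classify_roles(hits_scores(m))
        by_node = dict(zip(roles["node"], roles["role"]))
        assert by_node["driver"] == "transmitter"
        assert by_node["follower"] == "receiver"

    def test_threshold_bounds_validated(self):
        from actiflow.infoflow import NodeScores

        scores = NodeScores(nodes=["a"], authority=np.array([1.0]), hub=np.array([1.0]))
        with pytest.raises(ValueError):
            classify_roles(scores, 0.0, 0.5)
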