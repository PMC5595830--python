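import numpy as np
import pandas as pd
import pytest

from actiflow.msm import (
    MicrostateAssignment,
    bootstrap,
    ck_test,
    classify_region,
    cluster_microstates,
    count_transitions,
    estimate_msm,
    implied_timescales,
    kinetic_evolution,
    macrostate_statistics,
    pcca_lump,
    _reversible_mle,
    _timescales_from_eigenvalues,
)
from actiflow.synthetic import (
    MarkovChainSpec,
    metastable_two_block_matrix,
    simulate_markov_chain,
)


def assignment_from(trajs, n_states, dt=1.0):
    return MicrostateAssignment(labels=list(trajs), n_states=n_states, frame_interval_ns=dt)


class TestClusterMicrostates:
    def test_each_distinct_point_gets_own_cluster(self):
        pts = np.array([[0.0, 0], [10, 0], [0, 10], [10, 10]])
        a = cluster_microstates([pts], k=4, seed=0)
        assert len(set(a.labels[0].tolist())) == 4

    def test_two_separated_blobs_partitioned_exactly(self):
        rng = np.random.default_rng(0)
        blob1 = rng.normal(size=(200, 2)) * 0.1
        blob2 = rng.normal(size=(150, 2)) * 0.1 + 50.0
        a = cluster_microstates([np.vstack([blob1, blob2])], k=2, seed=1)
        l = a.labels[0]
        assert len(set(l[:200])) == 1 and len(set(l[200:])) == 1 and l[0] != l[-1]

    def test_fewer_frames_than_clusters_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            cluster_microstates([np.zeros((5, 2))], k=10, seed=0)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(500, 3))
        a = cluster_microstates([x], k=20, seed=3)
        b = cluster_microstates([x], k=20, seed=3)
        assert np.array_equal(a.labels[0], b.labels[0])


class TestEstimateMsm:
    def test_two_state_closed_form(self):
        # counts [[90,10],[20,80]] -> already reversible; T rows normalize
        counts = np.array([[90.0, 10.0], [20.0, 80.0]])
        T, pi = _reversible_mle(counts)
        np.testing.assert_allclose(T, [[0.9, 0.1], [0.2, 0.8]], atol=1e-9)
        np.testing.assert_allclose(pi, [2 / 3, 1 / 3], atol=1e-9)

    def test_block_diagonal_trims_to_larger_block(self):
        t1 = np.array([0, 1] * 200)  # states 0-1
        t2 = np.array([2, 3] * 50)  # states 2-3, fewer counts
        with pytest.warns(UserWarning, match="trimmed"):
            m = estimate_msm(assignment_from([t1, t2], 4), lag=1)
        assert set(m.active_set.tolist()) == {0, 1}

    def test_reversible_estimate_is_local_likelihood_optimum(self):
        rng = np.random.default_rng(4)
        traj = simulate_markov_chain(
            MarkovChainSpec(metastable_two_block_matrix(), 20_000, seed=5)
        )
        m = estimate_msm(assignment_from([traj], 4), lag=1)
        C = m.counts[np.ix_(m.active_set, m.active_set)]

        def loglik(T):
            with np.errstate(divide="ignore"):
                L = C * np.log(np.where(T > 0, T, 1.0))
            return L[C > 0].sum()

        base = loglik(m.transition_matrix)
        pi = m.stationary_distribution
        for _ in range(25):
            # random detailed-balance-preserving perturbation of the flux matrix
            F = pi[:, None] * m.transition_matrix
            P = rng.normal(scale=1e-4, size=F.shape)
            P = 0.5 * (P + P.T)
            F2 = np.clip(F + P, 1e-12, None)
            T2 = F2 / F2.sum(axis=1, keepdims=True)
            assert loglik(T2) <= base + 1e-9

    def test_detailed_balance_asserted_on_every_estimate(self):
        traj = simulate_markov_chain(
            MarkovChainSpec(metastable_two_block_matrix(6, 0.9, 0.1), 30_000, seed=6)
        )
        m = estimate_msm(assignment_from([traj], 6), lag=2)
        pi, T = m.stationary_distribution, m.transition_matrix
        np.testing.assert_allclose(pi[:, None] * T, (pi[:, None] * T).T, rtol=1e-7, atol=1e-14)

    def test_no_transitions_at_lag_rejected(self):
        with pytest.raises(ValueError, match="no transitions"):
            estimate_msm(assignment_from([np.array([0])], 1), lag=1)


class TestImpliedTimescales:
    def test_closed_form_from_eigenvalue(self):
        ts = _timescales_from_eigenvalues(np.array([1.0, 0.7]), lag=1, n_timescales=1,
                                          frame_interval_ns=1.0)
        assert ts[0] == pytest.approx(-1 / np.log(0.7), rel=1e-12)

    def test_near_identity_chain_flagged_infinite(self):
        ts = _timescales_from_eigenvalues(np.array([1.0, 1.0 - 1e-14]), lag=1,
                                          n_timescales=1, frame_interval_ns=1.0)
        assert np.isinf(ts[0])

    def test_markovian_data_gives_flat_curve_within_quartiles(self):
        T = metastable_two_block_matrix(4, 0.9, 0.1)
        trajs = [
            simulate_markov_chain(MarkovChainSpec(T, 20_000, seed=10 + i)) for i in range(8)
        ]
        curve = implied_timescales(assignment_from(trajs, 4), lags=[1, 2, 5, 10],
                                   n_timescales=1, n_bootstrap=30, seed=1)
        t2 = curve.timescales[:, 0]
        iqr = curve.q3[:, 0] - curve.q1[:, 0]
        # flat: each lag's estimate deviates from the lag-1 estimate by less
        # than a few bootstrap interquartile ranges
        assert np.all(np.abs(t2 - t2[0]) <= 3 * iqr + 0.05 * t2[0])

    def test_invariant_to_trajectory_order(self):
        T = metastable_two_block_matrix()
        trajs = [simulate_markov_chain(MarkovChainSpec(T, 5000, seed=s)) for s in (1, 2, 3)]
        c1 = implied_timescales(assignment_from(trajs, 4), lags=[1, 3], n_timescales=1)
        c2 = implied_timescales(assignment_from(trajs[::-1], 4), lags=[1, 3], n_timescales=1)
        np.testing.assert_allclose(c1.timescales, c2.timescales, rtol=1e-10)


class TestCkTest:
    def test_markov_data_self_consistent(self):
        T = metastable_two_block_matrix(4, 0.95, 0.05)
        trajs = [simulate_markov_chain(MarkovChainSpec(T, 50_000, seed=20 + i)) for i in range(4)]
        a = assignment_from(trajs, 4)
        m = estimate_msm(a, lag=1)
        table = ck_test(m, a, sets=[[0, 1], [2, 3]], multiples=(1, 2, 5, 10), n_bootstrap=20)
        for _, row in table.iterrows():
            width = max(row["observed_q3"] - row["observed_q1"], 0.02)
            assert abs(row["predicted"] - row["observed"]) < 3 * width

    def test_multiple_one_matches_by_construction(self):
        traj = simulate_markov_chain(MarkovChainSpec(metastable_two_block_matrix(), 20_000, seed=30))
        a = assignment_from([traj], 4)
        m = estimate_msm(a, lag=1)
        t = ck_test(m, a, sets=[[0, 1]], multiples=(1,))
        assert t["predicted"].iloc[0] == pytest.approx(t["observed"].iloc[0], abs=1e-9)

    def test_period_three_cycle_violates_ck(self):
        # deterministic 0->1->2->0 cycle lumped into {0,1} vs {2}: the lag-1
        # model cannot reproduce the lag-3 deterministic return
        traj = np.tile([0, 1, 2], 4000)
        a = assignment_from([traj], 3)
        m = estimate_msm(a, lag=1)
        t = ck_test(m, a, sets=[[0, 1]], multiples=(1, 3))
        row = t[t["multiple"] == 3].iloc[0]
        assert abs(row["predicted"] - row["observed"]) > 0.1

    def test_overlapping_sets_rejected(self):
        traj = np.array([0, 1, 0, 1] * 100)
        a = assignment_from([traj], 2)
        m = estimate_msm(a, lag=1)
        with pytest.raises(ValueError, match="disjoint"):
            ck_test(m, a, sets=[[0], [0, 1]])


class TestPccaLump:
    def test_identity_lumping_when_m_equals_k(self):
        traj = simulate_markov_chain(MarkovChainSpec(metastable_two_block_matrix(), 20_000, seed=40))
        m = estimate_msm(assignment_from([traj], 4), lag=1)
        macro = pcca_lump(m, 4)
        assert macro.n_macrostates == 4
        assert len(set(macro.microstate_to_macrostate.tolist())) == 4

    def test_two_block_chain_recovers_blocks(self):
        T = metastable_two_block_matrix(4, 0.98, 0.02)
        traj = simulate_markov_chain(MarkovChainSpec(T, 100_000, seed=41))
        m = estimate_msm(assignment_from([traj], 4), lag=1)
        macro = pcca_lump(m, 2)
        crisp = macro.microstate_to_macrostate
        blocks = [set(m.active_set[crisp == j].tolist()) for j in range(2)]
        assert {frozenset(b) for b in blocks} == {frozenset({0, 1}), frozenset({2, 3})}
        assert macro.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_macrostate_probabilities_sum_of_member_pi(self):
        T = metastable_two_block_matrix(6, 0.9, 0.1)
        traj = simulate_markov_chain(MarkovChainSpec(T, 50_000, seed=42))
        m = estimate_msm(assignment_from([traj], 6), lag=1)
        macro = pcca_lump(m, 2)
        for j in range(2):
            expected = m.stationary_distribution[macro.members(j)].sum()
            assert macro.probabilities[j] == pytest.approx(expected, rel=1e-9)


class TestMacrostateStatistics:
    def setup_model(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])  # pi = (2/3, 1/3)
        traj = simulate_markov_chain(MarkovChainSpec(T, 50_000, seed=50))
        a = assignment_from([traj], 2)
        m = estimate_msm(a, lag=1)
        macro = pcca_lump(m, 1)
        return a, m, macro

    def test_identical_trace_values_give_that_mean(self):
        a, m, macro = self.setup_model()
        trace = np.full(a.n_frames_total, 7.5)
        stats = macrostate_statistics(macro, m, {"v": trace}, a)
        assert stats["v_mean"].iloc[0] == pytest.approx(7.5)

    def test_pi_weighted_average_of_two_microstates(self):
        a, m, macro = self.setup_model()
        labels = np.concatenate(a.labels)
        trace = labels.astype(float)  # value = microstate id (0 or 1)
        stats = macrostate_statistics(macro, m, {"v": trace}, a)
        pi = m.stationary_distribution
        assert stats["v_mean"].iloc[0] == pytest.approx(pi[1], abs=1e-9)

    def test_uniform_weights_reduce_to_arithmetic_mean(self):
        # symmetric chain: pi uniform, so the weighted mean is the plain mean
        T = np.array([[0.8, 0.2], [0.2, 0.8]])
        traj = simulate_markov_chain(MarkovChainSpec(T, 50_000, seed=51))
        a = assignment_from([traj], 2)
        m = estimate_msm(a, lag=1)
        macro = pcca_lump(m, 1)
        labels = np.concatenate(a.labels).astype(float)
        stats = macrostate_statistics(macro, m, {"v": labels}, a)
        micro_means = [labels[labels == 0].mean(), labels[labels == 1].mean()]
        pi = m.stationary_distribution
        assert stats["v_mean"].iloc[0] == pytest.approx(float(pi @ micro_means), abs=1e-9)


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "d,r,expected",
        [
            (9.0, 1.0, "inactive"),
            (10.0, 2.5, "inactive"),  # boundary inclusive
            (14.0, 1.0, "intermediate_I"),
            (14.0, 3.5, "active"),
            (11.5, 3.5, "intermediate_II"),
        ],
    )
    def test_grid(self, d, r, expected):
        assert classify_region(d, r) == expected

    def test_missing_statistic_rejected(self):
        with pytest.raises(ValueError):
            classify_region(np.nan, 1.0)


class TestKineticEvolution:
    def test_stationary_start_stays_constant(self):
        T = metastable_two_block_matrix(4, 0.9, 0.1)
        traj = simulate_markov_chain(MarkovChainSpec(T, 100_000, seed=60))
        m = estimate_msm(assignment_from([traj], 4), lag=1)
        macro = pcca_lump(m, 2)
        # start from the full stationary distribution: emulate by a one-
        # macrostate lump, whose restricted pi is pi itself
        full = pcca_lump(m, 1)
        evo = kinetic_evolution(m, full, 0, horizon=20)
        assert np.allclose(evo["macrostate_0"], 1.0, atol=1e-12)

    def test_two_state_closed_form(self):
        counts = np.array([[90.0, 10.0], [20.0, 80.0]])
        T, pi = _reversible_mle(counts)
        traj = simulate_markov_chain(MarkovChainSpec(np.array([[0.9, 0.1], [0.2, 0.8]]), 20_000, seed=61))
        a = assignment_from([traj], 2)
        m = estimate_msm(a, lag=1)
        macro = pcca_lump(m, 2)
        src = int(macro.microstate_to_macrostate[0])
        evo = kinetic_evolution(m, macro, src, horizon=30)
        pi0 = m.stationary_distribution[0]
        lam2 = m.eigenvalues[1]
        occ0 = evo[f"macrostate_{src}"].to_numpy()
        t = np.arange(31)
        np.testing.assert_allclose(occ0, pi0 + (1 - pi0) * lam2**t, atol=1e-9)

    def test_occupancies_conserve_probability(self):
        T = metastable_two_block_matrix(4, 0.9, 0.1)
        traj = simulate_markov_chain(MarkovChainSpec(T, 50_000, seed=62))
        m = estimate_msm(assignment_from([traj], 4), lag=1)
        macro = pcca_lump(m, 2)
        evo = kinetic_evolution(m, macro, 0, horizon=25)
        sums = evo[[f"macrostate_{j}" for j in range(2)]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-10)


class TestBootstrap:
    def test_constant_estimator_gives_degenerate_quartiles(self):
        res = bootstrap(lambda subset: np.array([4.2]), list(range(10)), n_samples=50, seed=0)
        assert res.q1[0] == res.q3[0] == 4.2

    def test_defaults_match_protocol(self):
        import inspect

        sig = inspect.signature(bootstrap)
        assert sig.parameters["n_samples"].default == 500
        assert sig.parameters["fraction"].default == 0.95

    def test_failures_recorded_and_excluded(self):
        calls = {"n": 0}

        def flaky(subset):
            calls["n"] += 1
            if calls["n"] % 3 == 0:
                raise RuntimeError("boom")
            return np.array([1.0])

        res = bootstrap(flaky, list(range(5)), n_samples=30, seed=1)
        assert res.n_failed > 0
        assert res.estimates.shape[0] + res.n_failed == 30

    def test_requires_two_trajectories(self):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap(lambda s: np.array([0.0]), [1], n_samples=5)


class TestParameterRecovery:
    def test_four_state_metastable_chain(self):
        """pi within 0.02 and t2 within 10% of analytic on a long trajectory."""
        T = metastable_two_block_matrix(4, 0.95, 0.05)
        vals = np.sort(np.linalg.eigvals(T).real)[::-1]
        t2_exact = -1.0 / np.log(vals[1])
        pi_exact = np.full(4, 0.25)
        traj = simulate_markov_chain(MarkovChainSpec(T, 1_000_000, seed=70))
        m = estimate_msm(assignment_from([traj], 4), lag=1)
        np.testing.assert_allclose(m.stationary_distribution, pi_exact, atol=0.02)
        t2_est = -1.0 / np.log(m.eigenvalues[1])
        assert abs(t2_est - t2_exact) / t2_exact < 0.10
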