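"""MSM core: counting, reversible MLE, timescales, CK test, free energies."""

import numpy as np
import pytest

from dimer_msm import (
    ck_test,
    cluster_microstates,
    count_and_connect,
    estimate_msm,
    estimate_reversible_transition_matrix,
    implied_timescales,
    macrostate_free_energies,
    simulate_markov_chain,
)
from dimer_msm.msm import count_transitions, largest_connected_set
from dimer_msm.synthetic import GroundTruthChain


class TestClustering:
    def test_k_equals_n_points_gives_zero_inertia(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 2))
        disc = cluster_microstates([X], k=12, seed=0)
        assert disc.inertia == pytest.approx(0.0, abs=1e-12)
        assert len(np.unique(disc.labels[0])) == 12

    def test_two_separated_blobs(self):
        """Blobs 20 sd apart: centers land within 0.1 sd of the blob means."""
        rng = np.random.default_rng(1)
        a = rng.normal(loc=0.0, scale=1.0, size=(4000, 2))
        b = rng.normal(loc=20.0, scale=1.0, size=(4000, 2))
        disc = cluster_microstates([np.concatenate([a, b])], k=2, seed=0)
        centers = disc.centers[np.argsort(disc.centers[:, 0])]
        np.testing.assert_allclose(centers[0], a.mean(0), atol=0.1)
        np.testing.assert_allclose(centers[1], b.mean(0), atol=0.1)

    def test_k_above_frame_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_microstates([np.zeros((5, 2))], k=10, seed=0)

    def test_labels_split_by_replica(self):
        rng = np.random.default_rng(2)
        reps = [rng.normal(size=(30, 2)), rng.normal(size=(50, 2))]
        disc = cluster_microstates(reps, k=4, seed=0)
        assert [len(l) for l in disc.labels] == [30, 50]


class TestCounting:
    def test_hand_counted_alternating_replica(self):
        C = count_transitions([np.array([0, 1, 0, 1])], lag_frames=1)
        np.testing.assert_array_equal(C, [[0, 2], [1, 0]])
        assert set(largest_connected_set(C)) == {0, 1}

    def test_disjoint_replicas_keep_larger_component(self):
        labels = [np.array([0, 1, 0, 1, 0]), np.array([2, 3, 4, 2, 3, 4, 2])]
        C, active = count_and_connect(labels, lag=1.0, frame_interval=1.0)
        assert set(active) == {2, 3, 4}

    def test_counts_never_cross_replica_boundaries(self):
        C_joint = count_transitions([np.array([0, 0]), np.array([1, 1])], 1)
        assert C_joint[0, 1] == 0 and C_joint[1, 0] == 0

    def test_empirical_frequencies_recover_truth(self, two_state_chain):
        """Row-normalized counts at the chain's own lag approach T within 3 SE."""
        (seq,) = simulate_markov_chain(two_state_chain, 300_000, 1, seed=4)
        C = count_transitions([seq], 1)
        T_emp = C / C.sum(axis=1, keepdims=True)
        T = two_state_chain.transition_matrix
        for i in range(2):
            for j in range(2):
                se = np.sqrt(T[i, j] * (1 - T[i, j]) / C[i].sum())
                assert abs(T_emp[i, j] - T[i, j]) < 3 * se


class TestReversibleEstimator:
    def test_symmetric_counts_give_uniform_chain(self):
        model = estimate_reversible_transition_matrix(np.full((2, 2), 5.0))
        np.testing.assert_allclose(model.transition_matrix, 0.5)
        np.testing.assert_allclose(model.stationary_distribution, 0.5)

    def test_detailed_balance_counts_are_fixed_point(self):
        """Counts already satisfying detailed balance: MLE equals the naive
        row-normalized estimate."""
        C = np.array([[50.0, 10.0, 2.0],
                      [10.0, 80.0, 6.0],
                      [2.0, 6.0, 20.0]])
        model = estimate_reversible_transition_matrix(C)
        np.testing.assert_allclose(model.transition_matrix,
                                   C / C.sum(1, keepdims=True), atol=1e-9)

    def test_recovers_known_reversible_matrix(self, reversible_three_state):
        """1e6-step chain: recovered T within 1e-2 entrywise of the truth."""
        chain = GroundTruthChain(reversible_three_state, 1.0,
                                 np.arange(12).reshape(3, 4) + 1.0, 0.3,
                                 ("bound", "bound", "unbound"))
        (seq,) = simulate_markov_chain(chain, 1_000_000, 1, seed=10)
        model = estimate_msm([seq], lag=1.0, frame_interval=1.0)
        np.testing.assert_allclose(model.transition_matrix,
                                   reversible_three_state, atol=1e-2)

    def test_detailed_balance_invariant(self, reversible_three_state):
        chain = GroundTruthChain(reversible_three_state, 1.0,
                                 np.arange(12).reshape(3, 4) + 1.0, 0.3,
                                 ("bound", "bound", "unbound"))
        (seq,) = simulate_markov_chain(chain, 50_000, 1, seed=11)
        model = estimate_msm([seq], lag=1.0, frame_interval=1.0)
        pi, T = model.stationary_distribution, model.transition_matrix
        flux = pi[:, None] * T
        np.testing.assert_allclose(flux, flux.T, rtol=1e-8, atol=1e-14)
        # pi is the leading left eigenvector
        np.testing.assert_allclose(pi @ T, pi, atol=1e-10)
        # reversible spectrum is real with lambda_1 = 1
        lam = model.eigenvalues()
        assert lam[0] == pytest.approx(1.0, abs=1e-10)

    def test_estimation_error_shrinks_with_data(self, reversible_three_state):
        chain = GroundTruthChain(reversible_three_state, 1.0,
                                 np.arange(12).reshape(3, 4) + 1.0, 0.3,
                                 ("bound", "bound", "unbound"))
        errs = []
        for n in (10_000, 1_000_000):
            (seq,) = simulate_markov_chain(chain, n, 1, seed=12)
            model = estimate_msm([seq], lag=1.0, frame_interval=1.0)
            errs.append(np.max(np.abs(model.transition_matrix
                                      - reversible_three_state)))
        assert errs[1] < errs[0]

    def test_rows_without_counts_rejected(self):
        with pytest.raises(ValueError):
            estimate_reversible_transition_matrix(
                np.array([[1.0, 0.0], [0.0, 0.0]]),
                active_set=np.array([0, 1]))


class TestImpliedTimescales:
    def test_closed_form_eigenvalue(self):
        """lambda_2 = 1/e at tau = 1 ns gives t_2 = 1 ns (and 0.5 at 5 ns
        gives 5/ln 2 = 7.213 ns) via a chain constructed to have that gap."""
        # 2-state symmetric chain with eigenvalues (1, 1 - 2p)
        for lam2, tau, expected in [(np.exp(-1), 1.0, 1.0),
                                    (0.5, 5.0, 5.0 / np.log(2))]:
            p = (1 - lam2) / 2
            T = np.array([[1 - p, p], [p, 1 - p]])
            ts = -tau / np.log(np.sort(np.linalg.eigvals(T))[0].real)
            assert ts == pytest.approx(expected, rel=1e-12)
            # and through the estimator on counts proportional to T
            model = estimate_reversible_transition_matrix(
                1e6 * T, lag_frames=1, lag_ns=tau,
                active_set=np.array([0, 1]))
            assert model.timescales_ns(1)[0] == pytest.approx(expected, rel=1e-6)

    def test_flat_in_lag_for_markov_data(self, reversible_three_state):
        """Markov data: implied timescales agree across lags within sampling
        error, and match the analytic -k tau / ln lambda(T^k)."""
        chain = GroundTruthChain(reversible_three_state, 1.0,
                                 np.arange(12).reshape(3, 4) + 1.0, 0.3,
                                 ("bound", "bound", "unbound"))
        labels = simulate_markov_chain(chain, 100_000, 5, seed=13)
        table = implied_timescales(labels, lags=[1.0, 2.0, 4.0],
                                   frame_interval=1.0, n_timescales=2)
        lam_true = np.sort(np.linalg.eigvals(reversible_three_state).real)[::-1]
        t_true = -1.0 / np.log(lam_true[1:])
        for row in table:
            np.testing.assert_allclose(row, t_true, rtol=0.15)


class TestCKTest:
    @pytest.fixture
    def block_model_and_labels(self):
        W = np.array([[10.0, 1.0, 0.05, 0.05],
                      [1.0, 10.0, 0.05, 0.05],
                      [0.05, 0.05, 10.0, 1.0],
                      [0.05, 0.05, 1.0, 10.0]])
        T = W / W.sum(1, keepdims=True)
        chain = GroundTruthChain(T, 1.0, np.arange(16).reshape(4, 4) + 1.0,
                                 0.3, ("bound",) * 2 + ("unbound",) * 2)
        labels = simulate_markov_chain(chain, 50_000, 4, seed=14)
        model = estimate_msm(labels, lag=1.0, frame_interval=1.0)
        sets = [np.array([0, 1]), np.array([2, 3])]
        return model, labels, sets

    def test_factor_one_identity(self, block_model_and_labels):
        model, labels, sets = block_model_and_labels
        res = ck_test(model, labels, sets, factors=[1], frame_interval=1.0)
        np.testing.assert_allclose(res.predicted[0], res.estimated[0],
                                   atol=1e-10)

    def test_self_consistency_on_markov_data(self, block_model_and_labels):
        """Data simulated from a Markov chain passes CK within ~5 bands."""
        model, labels, sets = block_model_and_labels
        res = ck_test(model, labels, sets, factors=[1, 2, 3, 4, 5],
                      frame_interval=1.0)
        assert np.all(np.abs(res.predicted - res.estimated)
                      <= 5 * res.error + 1e-9)
        assert np.all((res.predicted >= 0) & (res.predicted <= 1))

    def test_hidden_state_negative_control(self):
        """A two-level hidden process discretized too coarsely violates CK."""
        # hidden 4-state chain: two metastable pairs; observation collapses
        # each pair AND one state of the other pair into aliased bins
        W = np.array([[20.0, 1.0, 0.01, 0.01],
                      [1.0, 20.0, 0.01, 0.01],
                      [0.01, 0.01, 20.0, 1.0],
                      [0.01, 0.01, 1.0, 20.0]])
        T = W / W.sum(1, keepdims=True)
        chain = GroundTruthChain(T, 1.0, np.arange(16).reshape(4, 4) + 1.0,
                                 0.3, ("bound",) * 2 + ("unbound",) * 2)
        labels = simulate_markov_chain(chain, 80_000, 2, seed=15)
        # aliasing: hidden states 1 and 2 merge into observed state 1
        obs = [np.where(seq == 2, 1, np.where(seq == 3, 2, seq)) for seq in labels]
        model = estimate_msm(obs, lag=1.0, frame_interval=1.0)
        sets = [np.array([0]), np.array([1]), np.array([2])]
        res = ck_test(model, obs, sets, factors=[1, 5, 10, 20],
                      frame_interval=1.0)
        assert res.max_deviation() > 10 * np.nanmax(res.error[0])

    def test_infeasible_factor_dropped(self, block_model_and_labels, caplog):
        import logging
        model, labels, sets = block_model_and_labels
        with caplog.at_level(logging.WARNING, logger="dimer_msm.msm"):
            res = ck_test(model, labels, sets, factors=[1, 10**6],
                          frame_interval=1.0)
        assert res.factors == [1]


class TestFreeEnergies:
    def test_single_macrostate_is_zero(self):
        pi = np.array([0.2, 0.3, 0.5])
        dg = macrostate_free_energies(pi, np.zeros(3, dtype=int), 310.0)
        assert dg[0] == pytest.approx(0.0, abs=1e-12)

    def test_equal_split_gives_equal_free_energy(self):
        pi = np.array([0.25, 0.25, 0.25, 0.25])
        dg = macrostate_free_energies(pi, np.array([0, 0, 1, 1]), 310.0)
        assert dg[0] == pytest.approx(dg[1])

    def test_80_20_split_at_310K(self):
        """Sum-pi (0.8, 0.2) at 310 K: ddG = RT ln 4 = 3.573 kJ/mol."""
        pi = np.array([0.8, 0.2])
        dg = macrostate_free_energies(pi, np.array([0, 1]), 310.0)
        assert dg[1] - dg[0] == pytest.approx(8.314462618e-3 * 310 * np.log(4),
                                              rel=1e-9)
        assert dg[1] - dg[0] == pytest.approx(3.573, abs=2e-3)

    def test_differences_invariant_to_pi_split_scale(self):
        """Free-energy differences depend only on probability ratios."""
        rng = np.random.default_rng(8)
        pi = rng.dirichlet(np.ones(6))
        assignment = np.array([0, 0, 1, 1, 2, 2])
        dg = macrostate_free_energies(pi, assignment, 310.0)
        base = dg - dg.min()
        # rescale pi within each macrostate (keeping totals) -> unchanged
        pi2 = pi.copy()
        pi2[0], pi2[1] = 0.9 * (pi[0] + pi[1]), 0.1 * (pi[0] + pi[1])
        dg2 = macrostate_free_energies(pi2, assignment, 310.0)
        np.testing.assert_allclose(dg2 - dg2.min(), base, atol=1e-12)

    def test_empty_macrostate_flagged_infinite(self):
        pi = np.array([0.5, 0.5])
        dg = macrostate_free_energies(pi, np.array([0, 2]), 310.0)
        assert np.isinf(dg[1])

    def test_unnormalized_pi_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            macrostate_free_energies(np.array([0.5, 0.6]),
                                     np.array([0, 1]), 310.0)
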