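"""Two-state diffusion: schedules, marginals, posteriors vs brute force."""

import json

import numpy as np
import pytest

from disco.diffusion import (EdgeCategorical, NoiseSchedule, ddim_posterior,
                             forward_marginal, make_schedule, posterior,
                             sample_state)


def brute_posterior(at: int, a0: int, K_step: np.ndarray, Qbar_prev: np.ndarray
                    ) -> np.ndarray:
    """Enumerate both values of the intermediate state (independent oracle)."""
    w = np.array([K_step[s, at] * Qbar_prev[a0, s] for s in (0, 1)])
    return w / w.sum()


class TestSchedules:
    def test_single_step_zero_beta_is_identity(self):
        sched = make_schedule(1, 0.0, 0.0)
        np.testing.assert_array_equal(sched.qbar(1), np.eye(2))

    def test_two_step_cumulative_kernel_by_hand(self):
        # Q(0.1) @ Q(0.2) = [[0.74, 0.26], [0.26, 0.74]]
        sched = make_schedule(2, 0.1, 0.2)
        np.testing.assert_allclose(sched.qbar(2),
                                   [[0.74, 0.26], [0.26, 0.74]], atol=1e-12)

    def test_default_schedule_reaches_uniform_horizon(self):
        sched = make_schedule(1000, 1e-4, 0.02)
        off = sched.qbar(1000)[0, 1]
        assert 0.49 <= off <= 0.5

    def test_kernel_algebra(self):
        sched = make_schedule(20, 0.01, 0.3)
        for t_lo, t_hi in [(0, 20), (3, 7), (10, 20), (5, 6)]:
            np.testing.assert_allclose(
                sched.qbar(t_lo) @ sched.qbar_between(t_lo, t_hi),
                sched.qbar(t_hi), atol=1e-12)

    def test_betas_monotone_and_tau_valid(self):
        for kind in ("linear", "cosine"):
            sched = make_schedule(100, 1e-3, 0.1, kind=kind, tau_count=10)
            assert np.all(np.diff(sched.betas) >= -1e-15)
            assert np.all(np.diff(sched.tau) > 0)
            assert sched.tau[-1] == 100
            assert np.all((sched.betas > 0) & (sched.betas <= 0.5))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            make_schedule(10, 0.2, 0.1)
        with pytest.raises(ValueError):
            make_schedule(10, 0.1, 0.7)
        with pytest.raises(ValueError):
            make_schedule(10, 0.1, 0.2, tau_count=11)

    def test_json_roundtrip(self):
        sched = make_schedule(10, 1e-3, 0.1, tau_count=4)
        back = NoiseSchedule.from_json(sched.to_json())
        np.testing.assert_allclose(back.betas, sched.betas)
        np.testing.assert_array_equal(back.tau, sched.tau)
        np.testing.assert_allclose(back.Qbar, sched.Qbar)


class TestForwardMarginal:
    def test_identity_limit_and_horizon(self):
        sched = make_schedule(50, 1e-3, 0.1)
        A0 = np.array([[1.0, 0.0], [0.0, 1.0]])
        m1 = forward_marginal(A0, 1, sched)
        np.testing.assert_allclose(m1.prob1,
                                   np.where(A0 > 0.5, 1 - 1e-3, 1e-3))
        mT = forward_marginal(A0, 50, sched)
        assert np.all(np.abs(mT.prob1 - 0.5) < 0.01)

    def test_hand_value_from_two_step_kernel(self):
        sched = make_schedule(2, 0.1, 0.2)
        m = forward_marginal(np.array([[1.0]]), 2, sched)
        np.testing.assert_allclose(m.prob1, [[0.74]], atol=1e-12)

    def test_t_out_of_range(self):
        sched = make_schedule(5, 1e-3, 0.1)
        with pytest.raises(ValueError):
            forward_marginal(np.eye(2), 0, sched)
        with pytest.raises(ValueError):
            forward_marginal(np.eye(2), 6, sched)


class TestSampleState:
    def test_degenerate_probabilities(self):
        zero = sample_state(EdgeCategorical(np.zeros((3, 3))), seed=0)
        one = sample_state(EdgeCategorical(np.ones((3, 3))), seed=0)
        np.testing.assert_array_equal(zero, 0)
        np.testing.assert_array_equal(one, 1)

    def test_mean_concentration(self):
        cat = EdgeCategorical(np.full((400, 250), 0.3))  # 1e5 edges
        s = sample_state(cat, seed=1)
        assert abs(s.mean() - 0.3) < 0.01
        np.testing.assert_array_equal(s, sample_state(cat, seed=1))


class TestPosterior:
    def test_matches_bruteforce_on_all_combinations(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            T = int(rng.integers(3, 30))
            bmin = float(rng.uniform(1e-4, 0.05))
            bmax = float(rng.uniform(bmin, 0.5))
            sched = make_schedule(T, bmin, bmax)
            t = int(rng.integers(2, T + 1))
            for at in (0, 1):
                for a0 in (0, 1):
                    got = posterior(np.array([[float(at)]]),
                                    np.array([[float(a0)]]), t, sched)
                    want = brute_posterior(at, a0, sched.Q[t - 1],
                                           sched.qbar(t - 1))
                    np.testing.assert_allclose(got.prob1[0, 0], want[1],
                                               atol=1e-12)

    def test_small_beta_concentrates_on_observed_state(self):
        sched = make_schedule(5, 1e-8, 1e-8)
        post = posterior(np.array([[1.0]]), np.array([[1.0]]), 3, sched)
        assert post.prob1[0, 0] > 1 - 1e-6
        post0 = posterior(np.array([[0.0]]), np.array([[0.0]]), 3, sched)
        assert post0.prob1[0, 0] < 1e-6

    def test_soft_a0_marginalization_identity(self):
        # sum over A_{t-1} of posterior * q(A_{t-1}|A0) == q(A_t|A0)
        sched = make_schedule(15, 1e-3, 0.2)
        rng = np.random.default_rng(1)
        A0 = (rng.random((4, 5)) < 0.3).astype(float)
        for t in (2, 7, 15):
            m_prev = forward_marginal(A0, t - 1, sched).prob1
            m_now = forward_marginal(A0, t, sched).prob1
            for at in (0, 1):
                At = np.full_like(A0, float(at))
                p1 = posterior(At, A0, t, sched).prob1
                beta = sched.betas[t - 1]
                # q(A_t = at) = sum_s q(at|s) m_prev(s)
                q_at = np.where(At > 0.5,
                                (1 - beta) * m_prev + beta * (1 - m_prev),
                                beta * m_prev + (1 - beta) * (1 - m_prev))
                want = np.where(At > 0.5, m_now, 1 - m_now)
                # Bayes: p1 * q(at) = q(at | s=1) m_prev(1)
                lik1 = (1 - beta) if at == 1 else beta
                np.testing.assert_allclose(p1 * q_at, lik1 * m_prev,
                                           atol=1e-12)

    def test_t_one_rejected(self):
        sched = make_schedule(5, 1e-3, 0.1)
        with pytest.raises(ValueError):
            posterior(np.eye(2), np.eye(2), 1, sched)


class TestDDIMPosterior:
    def test_reduces_to_single_step_for_consecutive_tau(self):
        sched = make_schedule(10, 1e-3, 0.2, tau_count=10)  # tau = 1..10
        rng = np.random.default_rng(2)
        At = (rng.random((3, 4)) < 0.5).astype(float)
        A0 = (rng.random((3, 4)) < 0.3).astype(float)
        for i in (2, 5, 10):
            got = ddim_posterior(At, A0, i, sched)
            want = posterior(At, A0, int(sched.tau[i - 1]), sched)
            np.testing.assert_allclose(got.prob1, want.prob1, atol=1e-12)

    def test_matches_bruteforce_with_gaps(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            T = int(rng.integers(6, 40))
            K = int(rng.integers(2, min(T, 8)))
            sched = make_schedule(T, 1e-3, float(rng.uniform(0.05, 0.5)),
                                  tau_count=K)
            K = len(sched.tau)
            i = int(rng.integers(2, K + 1))
            t_lo, t_hi = int(sched.tau[i - 2]), int(sched.tau[i - 1])
            for at in (0, 1):
                for a0 in (0, 1):
                    got = ddim_posterior(np.array([[float(at)]]),
                                         np.array([[float(a0)]]), i, sched)
                    want = brute_posterior(
                        at, a0, sched.qbar_between(t_lo, t_hi),
                        sched.qbar(t_lo))
                    np.testing.assert_allclose(got.prob1[0, 0], want[1],
                                               atol=1e-12)

    def test_symmetric_soft_a0_at_horizon(self):
        # with a long, well-mixed jump the posterior stays symmetric
        sched = make_schedule(50, 1e-3, 0.1, tau_count=2)
        soft = EdgeCategorical(np.full((2, 2), 0.5))
        post = ddim_posterior(np.ones((2, 2)), soft, 2, sched)
        np.testing.assert_allclose(post.prob1, 0.5, atol=0.02)

    def test_index_bounds(self):
        sched = make_schedule(10, 1e-3, 0.2, tau_count=5)
        with pytest.raises(ValueError):
            ddim_posterior(np.eye(2), np.eye(2), 1, sched)
        with pytest.raises(ValueError):
            ddim_posterior(np.eye(2), np.eye(2), 6, sched)


def test_ancestral_sampling_matches_forward_marginals():
    """Reverse simulation with the true A_0 reproduces forward marginals."""
    sched = make_schedule(8, 0.05, 0.3)
    a0 = 1.0
    n = 10_000
    A0 = np.full((n, 1), a0)
    rng = np.random.default_rng(0)
    # forward horizon marginal, then reverse via exact posteriors
    state = sample_state(forward_marginal(A0, sched.T, sched), seed=1)
    for t in range(sched.T, 1, -1):
        post = posterior(state, A0, t, sched)
        state = sample_state(post, seed=int(rng.integers(2 ** 31)))
        # compare empirical marginal at t-1 against the forward marginal
        want = forward_marginal(A0, t - 1, sched).prob1[0, 0]
        tv = abs(state.mean() - want)
        assert tv < 0.02
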