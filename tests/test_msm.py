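"""MSM estimation, diagnostics, GMRQ cross-validation and reconstruction."""

import numpy as np
import pytest

from _oracles import (
    hand_count_transitions,
    lumped_two_state_chain,
    markov_log_likelihood,
)

from loopmsm.msm import (
    CountMatrix,
    MarkovStateModel,
    ck_test,
    count_matrix,
    count_metastable,
    eigenvalues_sorted,
    gmrq_cross_validate,
    implied_timescales,
    score_msm,
    split_folds,
    stationary_distribution,
    synthesize_trajectory,
    frames_by_state,
    transition_matrix,
    trim_to_connected,
)
from loopmsm.synthetic import sample_discrete_chain


class TestCounting:
    def test_lag_one_hand_enumeration(self):
        C = count_matrix([np.array([0, 0, 1, 1, 0])], lag=1)
        assert np.array_equal(C.counts, [[1, 1], [1, 1]])

    def test_lag_two_hand_enumeration(self):
        C = count_matrix([np.array([0, 0, 1, 1, 0])], lag=2)
        assert np.array_equal(C.counts, [[0, 2], [1, 0]])

    def test_counting_never_crosses_trajectory_boundaries(self):
        a, b = np.array([0, 0, 1]), np.array([1, 0, 0])
        separate = count_matrix([a, b], lag=1).counts
        joined = count_matrix([np.concatenate([a, b])], lag=1).counts
        # the boundary pair (1 -> 1) appears only in the joined version
        assert joined[1, 1] == separate[1, 1] + 1

    def test_strided_counts_subset_of_sliding(self):
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0])
        sliding = count_matrix([labels], lag=2, mode="sliding").counts
        strided = count_matrix([labels], lag=2, mode="strided").counts
        assert np.all(strided <= sliding)
        assert strided.sum() == len(labels[::2]) - 1

    def test_all_trajectories_too_short_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            count_matrix([np.array([0, 1])], lag=5)


class TestTrim:
    def test_fully_connected_unchanged(self):
        C = CountMatrix(np.ones((3, 3)), lag=1)
        out = trim_to_connected(C)
        assert np.array_equal(out.counts, C.counts)
        assert np.array_equal(out.active_set, [0, 1, 2])

    def test_block_diagonal_keeps_heavier_block(self):
        counts = np.zeros((5, 5))
        counts[:2, :2] = 1.0  # 2-state block
        counts[2:, 2:] = 5.0  # 3-state block with more counts
        out = trim_to_connected(CountMatrix(counts, lag=1))
        assert np.array_equal(out.active_set, [2, 3, 4])
        assert out.counts.shape == (3, 3)

    def test_single_state_with_self_count(self):
        out = trim_to_connected(CountMatrix(np.array([[4.0]]), lag=1))
        assert np.array_equal(out.counts, [[4.0]])


class TestTransitionMatrix:
    def test_row_normalisation_by_hand(self):
        C = CountMatrix(np.array([[2.0, 2], [1, 1]]), lag=1)
        T = transition_matrix(C, reversible=False)
        assert np.allclose(T, [[0.5, 0.5], [0.5, 0.5]])

    def test_symmetric_counts_reversible_equals_row_normalisation(self):
        counts = np.array([[4.0, 2, 1], [2, 6, 3], [1, 3, 5]])
        C = CountMatrix(counts, lag=1)
        assert np.allclose(
            transition_matrix(C, reversible=True),
            transition_matrix(C, reversible=False),
            atol=1e-9,
        )

    @pytest.mark.parametrize("seed", range(3))
    def test_reversible_mle_detailed_balance_and_likelihood(self, seed):
        """The reversible MLE satisfies detailed balance to 1e-8 and beats the
        naive symmetrised detailed-balance candidate in likelihood."""
        rng = np.random.default_rng(seed)
        counts = rng.integers(1, 30, size=(4, 4)).astype(float)
        C = CountMatrix(counts, lag=1)
        T = transition_matrix(C, reversible=True)
        pi = stationary_distribution(T)
        assert np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)) < 1e-8
        naive = (counts + counts.T) / (counts + counts.T).sum(axis=1, keepdims=True)
        assert markov_log_likelihood(counts, T) >= markov_log_likelihood(counts, naive) - 1e-9

    def test_zero_row_rejected(self):
        C = CountMatrix(np.array([[1.0, 1], [0, 0]]), lag=1)
        with pytest.raises(ValueError, match="zero row"):
            transition_matrix(C, reversible=False)


class TestStationary:
    def test_symmetric_chain_is_uniform(self):
        pi = stationary_distribution(np.array([[0.9, 0.1], [0.1, 0.9]]))
        assert np.allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_asymmetric_chain_solved_by_hand(self):
        pi = stationary_distribution(np.array([[0.9, 0.1], [0.2, 0.8]]))
        assert np.allclose(pi, [2 / 3, 1 / 3], atol=1e-12)
        assert pi.sum() == pytest.approx(1.0, abs=1e-12)

    def test_reducible_matrix_rejected(self):
        with pytest.raises(ValueError, match="reducible"):
            stationary_distribution(np.eye(2))


class TestImpliedTimescales:
    def test_two_state_closed_form(self):
        """lambda_2 = 0.8 at a 20 ns step gives t2 = -20/ln 0.8 = 89.63 ns."""
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        d = sample_discrete_chain(T, 10**6, seed=2, lag_unit=20.0)
        its = implied_timescales([d.labels], lags=[1], k_eigs=1, dt=20.0)
        assert its.valid[0, 0]
        assert its.timescales[0, 0] == pytest.approx(-20.0 / np.log(0.8), rel=0.05)

    def test_markovian_chain_is_lag_independent(self):
        T = np.array([[0.97, 0.03], [0.02, 0.98]])
        dtrajs = [sample_discrete_chain(T, 10**5, seed=s).labels for s in range(4)]
        its = implied_timescales(dtrajs, lags=[1, 2, 4, 8], k_eigs=1)
        t2 = its.timescales[:, 0]
        assert np.all(its.valid[:, 0])
        assert (t2.max() - t2.min()) / t2.mean() < 0.15

    def test_timescale_diverges_as_lambda_approaches_one(self):
        # exact expected counts reproduce T exactly, isolating the formula
        taus = []
        for lam in (0.9, 0.99, 0.999):
            p = (1 - lam) / 2
            T = np.array([[1 - p, p], [p, 1 - p]])
            C = CountMatrix(1000 * 0.5 * T, lag=1)
            That = transition_matrix(C, reversible=True)
            lam_hat = np.real(eigenvalues_sorted(That, 2)[1])
            taus.append(-1.0 / np.log(lam_hat))
        assert taus[0] < taus[1] < taus[2]

    def test_invalid_eigenvalues_flagged_not_dropped(self):
        # period-2 deterministic chain: lambda_2 = -1 cannot give a timescale
        d = np.array([0, 1] * 50)
        its = implied_timescales([d], lags=[1], k_eigs=1, reversible=False)
        assert not its.valid[0, 0]
        assert np.isnan(its.timescales[0, 0])


class TestChapmanKolmogorov:
    def test_markovian_data_passes(self):
        T = np.array([[0.95, 0.05], [0.1, 0.9]])
        dtrajs = [sample_discrete_chain(T, 10**5, seed=s).labels for s in range(3)]
        out = ck_test(dtrajs, lag=1, factors=[2, 3])
        # sampling-error scale for ~1e5 transitions is ~3e-3
        assert out["deviation"][2] < 0.01
        assert out["deviation"][3] < 0.01

    def test_deterministic_cycle_is_exact(self):
        d = np.array([0, 1, 2] * 40)
        out = ck_test([d], lag=1, factors=[2], reversible=False)
        assert out["deviation"][2] == pytest.approx(0.0, abs=1e-12)

    def test_hidden_state_construction_fails_ck(self):
        """Lumping a gateway hidden state produces memory: the exact lumped
        chain violates Chapman-Kolmogorov and the sampled test detects it."""
        T_h = np.array([[0.9, 0.1, 0.0], [0.45, 0.1, 0.45], [0.0, 0.1, 0.9]])
        lump = np.array([0, 0, 1])
        L1 = lumped_two_state_chain(T_h, lump, 1)
        L2 = lumped_two_state_chain(T_h, lump, 2)
        exact_dev = np.max(np.abs(np.linalg.matrix_power(L1, 2) - L2))
        assert exact_dev > 0.02  # genuinely non-Markovian by construction
        hidden = sample_discrete_chain(T_h, 2 * 10**5, seed=3).labels
        out = ck_test([lump[hidden]], lag=1, factors=[2], reversible=False)
        assert out["deviation"][2] == pytest.approx(exact_dev, abs=0.01)
        assert out["deviation"][2] > 0.02

    def test_insufficient_data_flagged_not_fatal(self):
        d = np.array([0, 1, 0, 1, 0, 1])
        out = ck_test([d], lag=2, factors=[2, 4])
        assert 4 in out["flagged"]


class TestMetastableCounting:
    def test_three_block_matrix(self):
        eps = 1e-3
        B = np.array([[0.7, 0.3], [0.3, 0.7]])
        T = np.zeros((6, 6))
        for b in range(3):
            T[2 * b : 2 * b + 2, 2 * b : 2 * b + 2] = B
        for b in range(2):  # symmetric coupling between adjacent blocks
            T[2 * b + 1, 2 * b + 2] += eps
            T[2 * b + 2, 2 * b + 1] += eps
        T /= T.sum(axis=1, keepdims=True)
        lam = np.sort(np.real(np.linalg.eigvals(T)))[::-1]
        assert lam[2] > 0.99 and lam[3] < 0.5  # direct eigensolve confirms the gap
        assert count_metastable(T) == 3

    def test_single_state(self):
        assert count_metastable(np.array([[1.0]])) == 1

    def test_fast_mixing_chain_is_one_state(self):
        T = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert count_metastable(T) == 1


class _IdentityPipeline:
    params = {"kind": "identity"}

    def fit(self, trajs):
        return self

    def transform(self, trajs):
        return [np.asarray(t, dtype=int) for t in trajs]


class _ScramblePipeline:
    """Random per-frame labels: destroys all kinetic information."""

    params = {"kind": "scramble"}

    def __init__(self, seed):
        self.seed = seed

    def fit(self, trajs):
        return self

    def transform(self, trajs):
        rng = np.random.default_rng(self.seed)
        return [rng.integers(0, 2, size=len(t)) for t in trajs]


def _two_state_trajs(lam, n_trajs, n_steps, seed0):
    p = (1 - lam) / 2
    T = np.array([[1 - p, p], [p, 1 - p]])
    return [
        sample_discrete_chain(T, n_steps, seed=seed0 + i).labels for i in range(n_trajs)
    ]


class TestGMRQ:
    LAM = 0.9

    def test_perfect_discretization_scores_one_plus_lambda(self):
        trajs = _two_state_trajs(self.LAM, 6, 20000, seed0=10)
        res = gmrq_cross_validate(trajs, _IdentityPipeline(), lag=1, n_folds=3, m_eigs=2, seed=0)
        assert np.all(res.fold_valid)
        assert res.mean_test_score == pytest.approx(1 + self.LAM, abs=0.02)

    def test_variational_bound_not_exceeded(self):
        trajs = _two_state_trajs(self.LAM, 6, 20000, seed0=30)
        res = gmrq_cross_validate(trajs, _IdentityPipeline(), lag=1, n_folds=3, m_eigs=2, seed=1)
        assert res.mean_test_score <= 1 + self.LAM + 0.05

    def test_perfect_beats_scrambled_across_seeds(self):
        wins = 0
        for seed in range(10):
            trajs = _two_state_trajs(self.LAM, 6, 4000, seed0=100 + 10 * seed)
            good = gmrq_cross_validate(
                trajs, _IdentityPipeline(), lag=1, n_folds=3, m_eigs=2, seed=seed
            )
            bad = gmrq_cross_validate(
                trajs, _ScramblePipeline(seed), lag=1, n_folds=3, m_eigs=2, seed=seed
            )
            if good.mean_test_score > bad.mean_test_score:
                wins += 1
        assert wins >= 9

    def test_leave_one_out_degenerates_gracefully(self):
        trajs = _two_state_trajs(self.LAM, 4, 5000, seed0=50)
        res = gmrq_cross_validate(trajs, _IdentityPipeline(), lag=1, n_folds=4, m_eigs=2, seed=2)
        assert np.all(np.isfinite(res.test_scores[res.fold_valid]))
        assert res.n_folds == 4

    def test_fold_split_never_straddles_trajectories(self):
        folds = split_folds(7, 3, seed=0)
        for train, test in folds:
            assert np.intersect1d(train, test).size == 0
            assert np.union1d(train, test).size == 7

    def test_score_msm_invalid_when_test_misses_active_states(self):
        train = [np.array([0, 1, 0, 1, 0, 1])]
        test = [np.array([2, 2, 2, 2])]
        _, te, ok = score_msm(train, test, lag=1, m_eigs=2)
        assert not ok and np.isnan(te)


class TestRecovery:
    T3 = np.array(
        [[0.90, 0.07, 0.03], [0.06, 0.90, 0.04], [0.02, 0.08, 0.90]]
    )

    def _max_error(self, n_steps, seed):
        d = sample_discrete_chain(self.T3, n_steps, seed=seed)
        C = trim_to_connected(count_matrix([d.labels], lag=1))
        That = transition_matrix(C, reversible=False)
        return float(np.max(np.abs(That - self.T3)))

    def test_recovery_error_small_at_large_n(self):
        errs = [self._max_error(10**5, seed) for seed in range(10)]
        assert np.median(errs) < 0.01

    def test_error_scales_as_inverse_sqrt_n(self):
        sizes = [10**3, 10**4, 10**5]
        med = [
            np.median([self._max_error(n, seed) for seed in range(10)]) for n in sizes
        ]
        slope = np.polyfit(np.log10(sizes), np.log10(med), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)


class TestSynthesis:
    def test_span_arithmetic_5000_steps_at_20ns_is_100us(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        idx = {0: np.array([[0, 0]]), 1: np.array([[0, 1]])}
        rec = synthesize_trajectory(T, idx, 5000, seed=0, lag_ns=20.0)
        assert rec.span_ns == pytest.approx(100_000.0)  # 100 us

    def test_absorbing_state_emits_only_its_frames(self):
        T = np.array([[1.0, 0.0], [0.5, 0.5]])
        idx = {0: np.array([[0, 0], [0, 1]]), 1: np.array([[0, 2]])}
        rec = synthesize_trajectory(T, idx, 200, seed=1, start=0)
        assert np.all(rec.states == 0)
        assert set(rec.frame_refs[:, 1]) <= {0, 1}

    def test_missing_frames_rejected_before_sampling(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError, match="no stored frames"):
            synthesize_trajectory(T, {0: np.array([[0, 0]])}, 10, seed=0)

    def test_transition_frequencies_match_generator(self):
        T = np.array([[0.85, 0.15], [0.25, 0.75]])
        idx = {0: np.array([[0, 0]]), 1: np.array([[0, 1]])}
        rec = synthesize_trajectory(T, idx, 10**5, seed=3)
        C = hand_count_transitions(rec.states, 1, 2)
        for i in range(2):
            row_n = C[i].sum()
            for j in range(2):
                se = np.sqrt(T[i, j] * (1 - T[i, j]) / row_n)
                assert abs(C[i, j] / row_n - T[i, j]) < 3 * se

    def test_stationary_occupancy_preserved(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        pi = stationary_distribution(T)
        idx = {0: np.array([[0, 0]]), 1: np.array([[0, 1]])}
        rec = synthesize_trajectory(T, idx, 10**5, seed=4)
        t2 = -1.0 / np.log(np.real(eigenvalues_sorted(T, 2)[1]))
        n_eff = rec.n_steps / (2 * t2)  # correlated samples
        for s in range(2):
            freq = np.mean(rec.states == s)
            se = np.sqrt(pi[s] * (1 - pi[s]) / n_eff)
            assert abs(freq - pi[s]) < 3 * se


class TestModelResults:
    def test_fit_and_summary(self):
        T = np.array([[0.97, 0.03], [0.02, 0.98]])
        dtrajs = [sample_discrete_chain(T, 30000, seed=s).labels for s in range(3)]
        res = MarkovStateModel(dtrajs, lag=1, dt=20.0).fit()
        assert res.n_states == 2
        assert np.allclose(res.transition_matrix.sum(axis=1), 1.0, atol=1e-10)
        text = res.summary()
        assert "lag time" in text and "eigenvalue" in text
        assert res.lag_ns == 20.0

    def test_results_sample_is_deterministic(self):
        T = np.array([[0.9, 0.1], [0.1, 0.9]])
        dtrajs = [sample_discrete_chain(T, 5000, seed=0).labels]
        res = MarkovStateModel(dtrajs, lag=1).fit()
        a = res.sample(100, seed=5)
        b = res.sample(100, seed=5)
        assert np.array_equal(a.labels, b.labels)

    def test_frames_by_state_partition(self):
        labels = np.array([0, 1, 0, 2, 1])
        prov = np.column_stack([np.zeros(5, int), np.arange(5)])
        idx = frames_by_state(labels, prov)
        assert sorted(idx) == [0, 1, 2]
        assert np.array_equal(idx[0][:, 1], [0, 2])
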