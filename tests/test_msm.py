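"""MSM estimation: counts, connectivity, reversible MLE, validation,
PCCA+, MFPTs."""

import numpy as np
import pytest
import scipy.optimize

from loopmsm.msm import (CountMatrix, TransitionModel,
                         _reversible_eigenvalues, ck_test,
                         cluster_microstates, count_transitions,
                         estimate_msm, estimate_reversible,
                         largest_connected_set, mfpt, mfpt_to_set, pcca_plus,
                         restrict_counts, timescales_from_model, vamp2_score)
from loopmsm.synthetic import make_system_spec, simulate_hidden_chain


def model_from_T(T, lag=1, stride=1.0):
    T = np.asarray(T, dtype=float)
    w, v = np.linalg.eig(T.T)
    if (np.abs(w - 1) < 1e-12).sum() > 1:   # reducible chain: uniform pi
        pi = np.full(T.shape[0], 1.0 / T.shape[0])
    else:
        pi = np.abs(np.real(v[:, np.argmin(np.abs(w - 1))]))
        pi /= pi.sum()
    return TransitionModel(lag=lag, active_set=np.arange(T.shape[0]), T=T,
                           pi=pi, eigenvalues=_reversible_eigenvalues(T, pi),
                           frame_stride_ns=stride)


def reversible_mle_oracle(C):
    """Independent constrained-optimization oracle for the reversible MLE:
    optimize the upper-triangular symmetric weights directly."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    iu = np.triu_indices(n)

    def neg_ll(z):
        X = np.zeros((n, n))
        X[iu] = np.exp(z)
        X = X + X.T - np.diag(np.diag(X))
        T = X / X.sum(axis=1, keepdims=True)
        mask = C > 0
        return -np.sum(C[mask] * np.log(T[mask]))

    z0 = np.log((C + C.T)[iu] + 0.5)
    res = scipy.optimize.minimize(neg_ll, z0, method="L-BFGS-B",
                                  options={"maxiter": 20_000, "ftol": 1e-15,
                                           "gtol": 1e-12})
    return -res.fun


def random_connected_counts(rng, n=3, scale=50):
    while True:
        C = rng.integers(0, scale, size=(n, n))
        C += np.eye(n, dtype=int)            # self counts
        c = CountMatrix(1, C)
        active, _, _ = largest_connected_set(c)
        if len(active) == n:
            return c


class TestCounting:
    def test_lag1_sliding(self):
        C = count_transitions([[0, 0, 1, 1, 0]], 1).counts
        assert C.tolist() == [[1, 1], [1, 1]]

    def test_lag2_sliding(self):
        C = count_transitions([[0, 0, 1, 1, 0]], 2).counts
        assert C.tolist() == [[0, 2], [1, 0]]

    def test_no_cross_trajectory_pairs(self):
        C = count_transitions([[0, 0], [1, 1]], 1).counts
        assert C.tolist() == [[1, 0], [0, 1]]

    def test_total_counts_sliding(self):
        seqs = [[0, 1, 0, 1, 1], [1, 0, 1]]
        C = count_transitions(seqs, 1).counts
        assert C.sum() == (5 - 1) + (3 - 1)

    def test_lag_too_long_raises(self):
        with pytest.raises(ValueError, match="lag"):
            count_transitions([[0, 1]], 5)


class TestConnectivity:
    def test_disconnected_tie_keeps_state_zero(self):
        c = CountMatrix(1, np.array([[5, 0], [0, 5]]))
        active, fs, _ = largest_connected_set(c)
        assert active.tolist() == [0]
        assert fs == 0.5

    def test_fully_connected_keeps_all(self):
        c = CountMatrix(1, np.array([[1, 1], [1, 1]]))
        active, fs, fc = largest_connected_set(c)
        assert active.tolist() == [0, 1]
        assert fs == 1.0 and fc == 1.0

    def test_count_tiebreak_keeps_heavier_component(self):
        c = CountMatrix(1, np.array([[2, 1], [0, 3]]))
        active, _, _ = largest_connected_set(c)
        assert active.tolist() == [1]


class TestReversibleMLE:
    def test_symmetric_counts_give_uniform(self):
        c = CountMatrix(1, np.array([[1, 1], [1, 1]]))
        m = estimate_reversible(c)
        assert np.allclose(m.T, 0.5)
        assert np.allclose(m.pi, 0.5)

    def test_detailed_balance_residual(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            c = random_connected_counts(rng, 4)
            m = estimate_reversible(c)
            flux = m.pi[:, None] * m.T
            assert np.abs(flux - flux.T).max() < 1e-8
            assert np.abs(m.T.sum(axis=1) - 1).max() < 1e-10

    @pytest.mark.parametrize("seed", range(20))
    def test_likelihood_matches_optimizer_oracle(self, seed):
        rng = np.random.default_rng(seed)
        c = random_connected_counts(rng, 3)
        m = estimate_reversible(c)
        ll = np.sum(c.counts[c.counts > 0]
                    * np.log(m.T[c.counts > 0]))
        ll_oracle = reversible_mle_oracle(c.counts)
        assert abs(ll - ll_oracle) < 1e-6

    def test_disconnected_input_raises(self):
        c = CountMatrix(1, np.array([[5, 0], [0, 5]]))
        with pytest.raises(ValueError, match="connected"):
            estimate_reversible(c)


class TestTimescalesAndScore:
    def test_two_state_closed_form(self):
        m = model_from_T([[0.9, 0.1], [0.1, 0.9]])
        ts = timescales_from_model(m)
        assert ts[0] == pytest.approx(-1 / np.log(0.8), abs=1e-10)
        assert ts[0] == pytest.approx(4.4814, abs=1e-4)

    def test_identity_like_reports_infinity(self):
        m = model_from_T(np.eye(3))
        assert np.isinf(timescales_from_model(m)).all()

    def test_unit_conversion(self):
        m = model_from_T([[0.9, 0.1], [0.1, 0.9]], stride=0.1)
        ts = timescales_from_model(m)
        assert ts[0] * m.frame_stride_ns == pytest.approx(0.44814, abs=1e-4)

    def test_vamp2_identity(self):
        m = model_from_T(np.eye(4))
        assert vamp2_score(m, 4) == pytest.approx(4.0)

    def test_vamp2_rank_one(self):
        m = model_from_T(np.tile([0.3, 0.7], (2, 1)))
        assert vamp2_score(m, 2) == pytest.approx(1.0, abs=1e-10)

    def test_vamp2_two_state(self):
        m = model_from_T([[0.9, 0.1], [0.1, 0.9]])
        assert vamp2_score(m, 2) == pytest.approx(1.64, abs=1e-10)


class TestCKTest:
    T_MARKOV = np.array([[0.95, 0.03, 0.02],
                         [0.02, 0.96, 0.02],
                         [0.01, 0.04, 0.95]])
    # 3-state chain whose {0,1} lumping strongly violates Markovianity:
    # state 0 is very sticky while state 1 is a fast transit state, so the
    # lumped state's survival is far from exponential.
    T_NONMARKOV = np.array([[0.999, 0.001, 0.0],
                            [0.004, 0.496, 0.50],
                            [0.0, 0.05, 0.95]])

    def _chain(self, T, n, seed):
        spec = make_system_spec(T.shape[0], 2, np.zeros((T.shape[0], 2, 3)),
                                1.0, T, seed=seed)
        return simulate_hidden_chain(spec, n, 0)

    def test_k1_prediction_equals_estimate(self):
        chain = self._chain(self.T_MARKOV, 20_000, 4)
        m, _, _, _ = estimate_msm([chain], 1)
        df = ck_test([chain], m, [[0], [1], [2]], k_values=[1])
        assert np.allclose(df["predicted"], df["estimated"], atol=1e-12)

    def test_markovian_data_passes(self):
        chain = self._chain(self.T_MARKOV, 100_000, 5)
        m, _, _, _ = estimate_msm([chain], 1)
        df = ck_test([chain], m, [[0], [1], [2]], k_values=range(1, 6))
        assert df["rel_deviation"].max() < 0.1

    def test_lumped_non_markov_process_fails(self):
        chain = self._chain(self.T_NONMARKOV, 100_000, 6)
        lumped = np.where(chain == 2, 1, 0)
        m, _, _, _ = estimate_msm([lumped], 1)
        df = ck_test([lumped], m, [[0], [1]], k_values=range(1, 6))
        assert df["rel_deviation"].max() > 0.1

    def test_insufficient_data_skipped_with_warning(self):
        chain = self._chain(self.T_MARKOV, 50, 7)
        m, _, _, _ = estimate_msm([chain], 1)
        with pytest.warns(UserWarning, match="skipping"):
            ck_test([chain], m, [[0], [1], [2]], k_values=[1, 100])


class TestPCCA:
    def block_chain(self, n_blocks, block_size, intra=0.45, inter=0.05):
        n = n_blocks * block_size
        T = np.zeros((n, n))
        for i in range(n):
            bi = i // block_size
            for j in range(n):
                bj = j // block_size
                if bi == bj:
                    T[i, j] = intra
                else:
                    T[i, j] = inter / (n - block_size)
            T[i] /= T[i].sum()
        return T

    def test_two_block_partition_recovered(self):
        T = self.block_chain(2, 2)
        coarse = pcca_plus(model_from_T(T), 2)
        crisp = coarse.crisp
        assert crisp[0] == crisp[1] and crisp[2] == crisp[3]
        assert crisp[0] != crisp[2]

    def test_three_block_partition_recovered(self):
        T = self.block_chain(3, 3)
        coarse = pcca_plus(model_from_T(T), 3)
        crisp = coarse.crisp
        for b in range(3):
            blk = crisp[3 * b: 3 * b + 3]
            assert (blk == blk[0]).all()
        assert len(set(crisp[::3].tolist())) == 3

    def test_m_equals_n_gives_identity(self):
        rng = np.random.default_rng(1)
        c = random_connected_counts(rng, 4)
        m = estimate_reversible(c)
        coarse = pcca_plus(m, 4)
        assert sorted(coarse.crisp.tolist()) == [0, 1, 2, 3]

    def test_membership_constraints(self):
        T = self.block_chain(2, 3, intra=0.4, inter=0.1)
        coarse = pcca_plus(model_from_T(T), 2)
        assert (coarse.memberships >= 0).all()
        assert np.allclose(coarse.memberships.sum(axis=1), 1.0)
        assert np.isclose(coarse.populations.sum(), 1.0)

    def test_populations_sorted_descending(self):
        T = self.block_chain(2, 2, intra=0.48, inter=0.02)
        coarse = pcca_plus(model_from_T(T), 2)
        assert (np.diff(coarse.populations) <= 1e-12).all()

    def test_bad_macrostate_count_raises(self):
        m = model_from_T([[0.9, 0.1], [0.1, 0.9]])
        with pytest.raises(ValueError):
            pcca_plus(m, 5)


class TestMFPT:
    def test_two_state_closed_form(self):
        m = model_from_T([[0.9, 0.1], [0.1, 0.9]])
        M = mfpt(m)
        assert M[0, 1] == pytest.approx(10.0)
        assert M[1, 0] == pytest.approx(10.0)

    def test_diagonal_zero(self):
        rng = np.random.default_rng(2)
        m = estimate_reversible(random_connected_counts(rng, 4))
        assert np.allclose(np.diag(mfpt(m)), 0.0)

    def test_matches_first_passage_simulation_oracle(self):
        T = np.array([[0.80, 0.10, 0.05, 0.05],
                      [0.10, 0.80, 0.05, 0.05],
                      [0.05, 0.05, 0.85, 0.05],
                      [0.05, 0.05, 0.05, 0.85]])
        m = model_from_T(T)
        analytic = mfpt(m)[0, 3]
        rng = np.random.default_rng(8)
        cum = np.cumsum(T, axis=1)
        n_samples = 20_000
        times = np.empty(n_samples)
        for s in range(n_samples):
            state, t = 0, 0
            while state != 3:
                state = int(np.searchsorted(cum[state], rng.random(),
                                            side="right"))
                t += 1
            times[s] = t
        se = times.std(ddof=1) / np.sqrt(n_samples)
        assert abs(times.mean() - analytic) < 3 * se

    def test_mfpt_to_set_zero_inside_target(self):
        m = model_from_T([[0.9, 0.1], [0.1, 0.9]])
        h = mfpt_to_set(m, np.array([1]))
        assert h[1] == 0.0 and h[0] == pytest.approx(10.0)


class TestMicrostates:
    def test_k1_center_is_mean(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(200, 2))
        micro = cluster_microstates([Y], 1, seed=0)
        assert np.allclose(micro.centers[0], Y.mean(axis=0), atol=1e-8)

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(4)
        a = rng.normal([-5, 0], 0.5, size=(500, 2))
        b = rng.normal([5, 0], 0.5, size=(500, 2))
        micro = cluster_microstates([np.vstack([a, b])], 2, seed=0)
        centers = micro.centers[np.argsort(micro.centers[:, 0])]
        se = 0.5 / np.sqrt(500)
        assert np.abs(centers[0] - [-5, 0]).max() < 3 * se
        assert np.abs(centers[1] - [5, 0]).max() < 3 * se
        lab = micro.labels[0]
        assert len(np.unique(lab[:500])) == 1 and len(np.unique(lab[500:])) == 1

    def test_determinism(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(300, 3))
        a = cluster_microstates([Y], 10, seed=42)
        b = cluster_microstates([Y], 10, seed=42)
        assert np.array_equal(a.labels[0], b.labels[0])

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_microstates([np.zeros((5, 2))], 10, seed=0)
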