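"""Gaussian HMM fitting, symmetric KL, Gini sparsity and the similarity score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from gaitsm.hmm import (
    GaussianHMM,
    calibrate_tau,
    correspondence_matrix,
    divergence_matrix,
    fit_hmm,
    gini_sparsity,
    hmm_similarity_score,
    hmm_sm_participant,
    make_training_windows,
    symmetric_kl_gaussian,
)


def toy_model(means, covs=None, rng=None):
    means = np.atleast_2d(np.asarray(means, dtype=float))
    N, d = means.shape
    if covs is None:
        covs = np.stack([np.eye(d)] * N)
    A = np.full((N, N), 1.0 / N)
    return GaussianHMM(
        transmat=A, means=means, covars=np.asarray(covs, float),
        startprob=np.full(N, 1.0 / N),
    )


def random_model(rng, n_states=4, dim=3, spread=6.0):
    means = rng.normal(0, spread, (n_states, dim))
    covs = []
    for _ in range(n_states):
        L = rng.normal(0, 0.5, (dim, dim))
        covs.append(L @ L.T + np.eye(dim))
    return toy_model(means, np.stack(covs))


class TestTrainingWindows:
    def test_sliding_window_count(self):
        cycles = [np.zeros((2, 3))] * 100
        assert len(make_training_windows(cycles, window=10, stride=1)) == 91

    def test_concatenated_lengths(self):
        rng = np.random.default_rng(0)
        cycles = [rng.normal(size=(2, rng.integers(3, 8))) for _ in range(12)]
        seqs = make_training_windows(cycles, window=4, stride=2)
        assert len(seqs) == 5
        for i, s in enumerate(seqs):
            member = cycles[2 * i : 2 * i + 4]
            assert s.shape == (2, sum(c.shape[1] for c in member))
            np.testing.assert_array_equal(s, np.concatenate(member, axis=1))

    def test_window_one_is_identity(self):
        cycles = [np.ones((3, k)) * k for k in range(2, 6)]
        seqs = make_training_windows(cycles, window=1, stride=1)
        assert len(seqs) == len(cycles)
        for s, c in zip(seqs, cycles):
            np.testing.assert_array_equal(s, c)

    def test_too_few_cycles(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_training_windows([np.zeros((2, 3))] * 5, window=10)


class TestSymmetricKL:
    def test_identical_gaussians_zero(self):
        mu = np.array([1.0, -2.0])
        S = np.array([[2.0, 0.3], [0.3, 1.0]])
        assert symmetric_kl_gaussian((mu, S), (mu, S)) == pytest.approx(0.0, abs=1e-12)

    def test_unit_mean_shift(self):
        # 1-D N(0,1) vs N(1,1): each direction contributes 1/2
        assert symmetric_kl_gaussian(
            (np.zeros(1), np.eye(1)), (np.ones(1), np.eye(1))
        ) == pytest.approx(1.0)

    def test_variance_ratio(self):
        # 1-D N(0,1) vs N(0,2): closed form (1/2)(1/2 + 2 - 2) = 1/4
        assert symmetric_kl_gaussian(
            (np.zeros(1), np.eye(1)), (np.zeros(1), 2.0 * np.eye(1))
        ) == pytest.approx(0.25)

    def test_monte_carlo_agreement(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            d = int(rng.integers(1, 3))
            g1 = (rng.normal(0, 1, d), np.diag(rng.uniform(0.5, 2.0, d)))
            g2 = (rng.normal(0, 1, d), np.diag(rng.uniform(0.5, 2.0, d)))
            closed = symmetric_kl_gaussian(g1, g2)
            n = 100_000
            x1 = rng.multivariate_normal(g1[0], g1[1], size=n)
            x2 = rng.multivariate_normal(g2[0], g2[1], size=n)
            lp = lambda x, g: multivariate_normal.logpdf(x, g[0], g[1])
            mc = np.mean(lp(x1, g1) - lp(x1, g2)) + np.mean(lp(x2, g2) - lp(x2, g1))
            assert mc == pytest.approx(closed, rel=0.02, abs=0.01)

    def test_singular_covariance_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            symmetric_kl_gaussian(
                (np.zeros(2), np.zeros((2, 2))), (np.zeros(2), np.eye(2))
            )

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            symmetric_kl_gaussian((np.zeros(1), np.eye(1)), (np.zeros(2), np.eye(2)))


class TestCorrespondence:
    def test_self_correspondence_identity_pattern(self):
        lam = toy_model([[0.0], [10.0], [20.0]])  # pairwise D_sym >= 100
        Q = correspondence_matrix(lam, lam, tau=1.0)
        np.testing.assert_allclose(Q, np.eye(3), atol=1e-6)

    def test_five_state_shape(self):
        rng = np.random.default_rng(1)
        Q = correspondence_matrix(random_model(rng, 5), random_model(rng, 5))
        assert Q.shape == (5, 5)
        assert np.all(Q > 0) and np.all(Q <= 1)

    def test_shared_emission_gives_all_ones(self):
        lam = toy_model([[1.0, 2.0]] * 4)
        Q = correspondence_matrix(lam, lam)
        np.testing.assert_array_equal(Q, np.ones((4, 4)))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimensions differ"):
            correspondence_matrix(toy_model([[0.0]]), toy_model([[0.0, 0.0]]))


class TestGini:
    @pytest.mark.parametrize("n", [2, 3, 5, 17])
    def test_uniform_is_zero(self, n):
        assert gini_sparsity(np.full(n, 3.2)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 9])
    def test_one_hot_is_one(self, n):
        u = np.zeros(n)
        u[1 % n] = 5.0
        assert gini_sparsity(u) == pytest.approx(1.0, abs=1e-12)

    def test_half_half_example(self):
        assert gini_sparsity(np.array([0.5, 0.5, 0.0, 0.0])) == pytest.approx(2 / 3)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gini_sparsity(np.zeros(4))

    @given(st.lists(st.floats(0.01, 100), min_size=3, max_size=10), st.data())
    @settings(max_examples=60, deadline=None)
    def test_mass_transfer_increases_sparsity(self, values, data):
        # moving mass from a smaller entry to a larger one never lowers H
        u = np.array(values)
        i, j = np.argsort(u)[[0, -1]]
        if i == j:
            return
        eps = data.draw(st.floats(0.0, float(u[i]) * 0.9))
        v = u.copy()
        v[i] -= eps
        v[j] += eps
        assert gini_sparsity(v) >= gini_sparsity(u) - 1e-9

    @given(st.lists(st.floats(0.01, 100), min_size=2, max_size=10),
           st.floats(0.01, 50))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, values, c):
        u = np.array(values)
        assert gini_sparsity(c * u) == pytest.approx(gini_sparsity(u), abs=1e-9)


class TestSimilarityScore:
    def test_self_similarity_of_separated_model(self):
        lam = toy_model([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0], [8.0, 8.0]])
        assert hmm_similarity_score(lam, lam) == pytest.approx(1.0, abs=1e-6)

    def test_state_permutation_invariance(self):
        rng = np.random.default_rng(7)
        lam = random_model(rng, 5)
        perm = rng.permutation(5)
        lam_p = GaussianHMM(
            transmat=lam.transmat[np.ix_(perm, perm)],
            means=lam.means[perm],
            covars=lam.covars[perm],
            startprob=lam.startprob[perm],
        )
        base = hmm_similarity_score(lam, lam)
        assert hmm_similarity_score(lam, lam_p) == pytest.approx(base, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a, b = random_model(rng, 4), random_model(rng, 6)
            assert hmm_similarity_score(a, b) == pytest.approx(
                hmm_similarity_score(b, a), abs=1e-12
            )

    def test_identical_emissions_give_zero(self):
        a = toy_model([[1.0, -1.0]] * 5)
        b = toy_model([[1.0, -1.0]] * 3)
        assert hmm_similarity_score(a, b) == 0.0

    def test_range_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            s = hmm_similarity_score(
                random_model(rng, int(rng.integers(2, 6))),
                random_model(rng, int(rng.integers(2, 6))),
                tau=float(rng.uniform(0.1, 50)),
            )
            assert 0.0 <= s <= 1.0

    def test_sparsity_formula_on_matrices(self):
        # the Eq.-style aggregate: permutation-like Q -> 1, constant Q -> 0
        def S_of(Q):
            rows = np.mean([gini_sparsity(r) for r in Q])
            cols = np.mean([gini_sparsity(c) for c in Q.T])
            return 0.5 * (rows + cols)

        assert S_of(np.eye(5)[np.random.default_rng(3).permutation(5)]) == pytest.approx(1.0)
        assert S_of(np.full((4, 6), 0.37)) == pytest.approx(0.0, abs=1e-12)
        rng = np.random.default_rng(5)
        for _ in range(50):
            Q = rng.uniform(0.01, 1, (int(rng.integers(2, 7)), int(rng.integers(2, 7))))
            assert 0.0 <= S_of(Q) <= 1.0


class TestFitHMM:
    def test_two_state_recovery(self):
        from hmmlearn.hmm import GaussianHMM as HL

        gen = HL(n_components=2, covariance_type="full", random_state=0)
        gen.startprob_ = np.array([0.5, 0.5])
        gen.transmat_ = np.array([[0.9, 0.1], [0.1, 0.9]])
        gen.means_ = np.array([[-3.0], [3.0]])
        gen.covars_ = np.ones((2, 1, 1))
        X, _ = gen.sample(2000, random_state=1)
        lam = fit_hmm([X.T], n_states=2, seed=0, n_restarts=3, n_iter=100)
        got = np.sort(lam.means.ravel())
        np.testing.assert_allclose(got, [-3.0, 3.0], atol=0.1)
        lam.validate()

    def test_rows_of_transmat_sum_to_one(self):
        rng = np.random.default_rng(2)
        seqs = [rng.normal(size=(2, 120)) for _ in range(3)]
        lam = fit_hmm(seqs, n_states=3, seed=1, n_restarts=1, n_iter=20)
        np.testing.assert_allclose(lam.transmat.sum(axis=1), 1.0, atol=1e-9)
        assert lam.startprob.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_input_floored_not_crashed(self):
        seqs = [np.full((2, 150), 1.3)]
        lam = fit_hmm(seqs, n_states=2, seed=0, n_restarts=1, n_iter=10)
        for S in lam.covars:
            assert np.linalg.eigvalsh(S).min() >= 1e-6 * (1 - 1e-9)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(4)
        lam = fit_hmm([rng.normal(size=(2, 150))], n_states=2, seed=0,
                      n_restarts=1, n_iter=10)
        back = GaussianHMM.from_dict(lam.to_dict())
        np.testing.assert_allclose(back.means, lam.means)
        np.testing.assert_allclose(back.covars, lam.covars)
        np.testing.assert_allclose(back.transmat, lam.transmat)


class TestParticipantScore:
    def test_score_within_unit_interval(self, patient_cycles):
        lam_c = fit_hmm(
            make_training_windows(patient_cycles, window=5, stride=3),
            n_states=3, seed=0, n_restarts=1, n_iter=20,
        )
        score = hmm_sm_participant(
            patient_cycles, lam_c, window=5, stride=3, n_states=3, seed=1,
            n_restarts=1, n_iter=20,
        )
        assert 0.0 <= score.S <= 1.0
        assert score.participant_id == "TT01"


class TestTauCalibration:
    def test_positive_and_scales_with_divergences(self):
        lam = toy_model([[0.0], [10.0], [20.0]])
        tau = calibrate_tau(lam, contrast=100.0)
        D = divergence_matrix(lam, lam)
        off = D[~np.eye(3, dtype=bool)]
        assert tau == pytest.approx(np.median(off) / np.log(100.0))

    def test_single_state_rejected(self):
        with pytest.raises(ValueError, match="single state"):
            calibrate_tau(toy_model([[0.0]]))
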