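import numpy as np
import pytest
from scipy import stats

from actiseq import Observations, SupervisedSequenceHMM


def random_model(rng, n_states, n_cont=2):
    """A random fitted-model surrogate with valid stochastic parameters."""
    m = SupervisedSequenceHMM()
    A = rng.random((n_states, n_states)) + 0.1
    m.transmat_ = A / A.sum(axis=1, keepdims=True)
    pi = rng.random(n_states) + 0.1
    m.startprob_ = pi / pi.sum()
    m.means_ = rng.normal(0, 2, (n_states, n_cont))
    m.variances_ = rng.uniform(0.3, 2.0, (n_states, n_cont))
    E = rng.random((n_states, n_states)) + 0.1
    m.emissionprob_ = E / E.sum(axis=1, keepdims=True)
    m.n_states_ = n_states
    m.n_continuous_ = n_cont
    return m


def random_obs(rng, n_states, T, n_cont=2):
    return Observations(
        rng.normal(0, 2, (T, n_cont)),
        rng.integers(1, n_states + 1, T),
    )


# ---------------------------------------------------------------- fitting


class TestSupervisedFit:
    def obs_for(self, states, lengths=None):
        states = np.asarray(states)
        return Observations(
            np.zeros((len(states), 1)), states, lengths=lengths or []
        )

    def test_bigram_counts_without_smoothing(self):
        states = [1, 1, 2, 2]
        m = SupervisedSequenceHMM(smoothing=0.0).fit(
            self.obs_for(states), states
        )
        np.testing.assert_allclose(m.transmat_, [[0.5, 0.5], [0.0, 1.0]])
        np.testing.assert_allclose(m.startprob_, [0.5, 0.5])

    def test_bigram_counts_with_laplace_smoothing(self):
        states = [1, 1, 2, 2]
        m = SupervisedSequenceHMM(smoothing=1.0).fit(
            self.obs_for(states), states
        )
        np.testing.assert_allclose(
            m.transmat_, [[0.5, 0.5], [1 / 3, 2 / 3]]
        )

    def test_subject_boundaries_excluded_from_bigrams(self):
        # two subjects (1,1) and (2,2): the 1->2 boundary is not a transition
        states = [1, 1, 2, 2]
        m = SupervisedSequenceHMM(smoothing=0.0).fit(
            self.obs_for(states, lengths=[2, 2]), states
        )
        np.testing.assert_allclose(m.transmat_, np.eye(2))

    def test_constant_continuous_part_gives_floored_variance(self):
        states = np.array([1, 1, 2, 2])
        X = np.array([[3.0], [3.0], [-1.0], [-1.0]])
        m = SupervisedSequenceHMM().fit(Observations(X, states), states)
        np.testing.assert_allclose(m.means_, [[3.0], [-1.0]])
        np.testing.assert_allclose(m.variances_, 1e-6)

    def test_single_observation_state_warns(self):
        states = np.array([1, 1, 1, 2])
        X = np.arange(4, dtype=float).reshape(-1, 1)
        with pytest.warns(UserWarning, match="single observation"):
            SupervisedSequenceHMM().fit(Observations(X, states), states)

    def test_missing_state_rejected(self):
        states = np.array([1, 1, 3, 3])
        with pytest.raises(ValueError):
            SupervisedSequenceHMM().fit(self.obs_for(states), states)

    def test_rows_stochastic_after_fit(self, rng):
        for _ in range(10):
            T = int(rng.integers(10, 60))
            N = int(rng.integers(2, 5))
            states = np.r_[np.arange(1, N + 1), rng.integers(1, N + 1, T)]
            obs = Observations(rng.standard_normal((len(states), 2)), states)
            m = SupervisedSequenceHMM(smoothing=rng.uniform(0, 2)).fit(
                obs, states
            )
            np.testing.assert_allclose(
                m.transmat_.sum(axis=1), 1.0, atol=1e-12
            )
            assert m.startprob_.sum() == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(
                m.emissionprob_.sum(axis=1), 1.0, atol=1e-12
            )


# ---------------------------------------------------------------- scoring


class TestLogJoint:
    def test_single_window(self, rng):
        m = random_model(rng, 3)
        obs = random_obs(rng, 3, 1)
        s = np.array([2])
        expected = (
            np.log(m.startprob_[1])
            + stats.norm.logpdf(
                obs.continuous[0], m.means_[1], np.sqrt(m.variances_[1])
            ).sum()
            + np.log(m.emissionprob_[1, obs.discrete[0] - 1])
        )
        assert m.log_joint(obs, s) == pytest.approx(expected)

    def test_uniform_chain_contribution(self, rng):
        m = random_model(rng, 2)
        m.transmat_ = np.full((2, 2), 0.5)
        m.startprob_ = np.array([0.5, 0.5])
        obs = random_obs(rng, 2, 3)
        states = np.array([1, 2, 1])
        emission = sum(
            stats.norm.logpdf(
                obs.continuous[t], m.means_[s - 1],
                np.sqrt(m.variances_[s - 1])
            ).sum()
            + np.log(m.emissionprob_[s - 1, obs.discrete[t] - 1])
            for t, s in enumerate(states)
        )
        assert m.log_joint(obs, states) == pytest.approx(
            3 * np.log(0.5) + emission
        )

    def test_matches_term_by_term_product_oracle(self, rng):
        """exp(log_joint) equals the direct product of transition and
        emission factors computed independently with scipy densities."""
        for _ in range(20):
            N = int(rng.integers(2, 4))
            T = int(rng.integers(1, 7))
            m = random_model(rng, N)
            obs = random_obs(rng, N, T)
            states = rng.integers(1, N + 1, T)
            prob = m.startprob_[states[0] - 1]
            for t in range(1, T):
                prob *= m.transmat_[states[t - 1] - 1, states[t] - 1]
            for t in range(T):
                s = states[t] - 1
                prob *= np.prod(
                    stats.norm.pdf(
                        obs.continuous[t], m.means_[s],
                        np.sqrt(m.variances_[s])
                    )
                )
                prob *= m.emissionprob_[s, obs.discrete[t] - 1]
            assert np.exp(m.log_joint(obs, states)) == pytest.approx(
                prob, rel=1e-9
            )

    def test_zero_probability_transition_returns_neg_inf(self):
        states = [1, 1, 2, 2]
        obs = Observations(np.zeros((4, 1)), np.asarray(states))
        m = SupervisedSequenceHMM(smoothing=0.0).fit(obs, states)
        assert m.log_joint(obs, np.array([2, 1, 1, 2])) == -np.inf


# ---------------------------------------------------------------- decoding


class TestViterbi:
    def test_single_state_constant_path(self, rng):
        m = random_model(rng, 1)
        obs = random_obs(rng, 1, 6)
        np.testing.assert_array_equal(m.viterbi(obs), np.ones(6))

    def test_uniform_chain_reduces_to_framewise_argmax(self, rng):
        m = random_model(rng, 3)
        m.transmat_ = np.full((3, 3), 1 / 3)
        m.startprob_ = np.full(3, 1 / 3)
        obs = random_obs(rng, 3, 25)
        framewise = np.argmax(m._emission_logprob(obs), axis=1) + 1
        np.testing.assert_array_equal(m.viterbi(obs), framewise)

    def test_agrees_with_brute_force_on_random_instances(self, rng):
        """Viterbi must return the global joint-probability maximizer:
        checked against exhaustive enumeration on 30 random models."""
        for _ in range(30):
            N = int(rng.integers(2, 5))
            T = int(rng.integers(1, 9))
            m = random_model(rng, N)
            obs = random_obs(rng, N, T)
            vit = m.viterbi(obs)
            brute = m.brute_force_decode(obs)
            np.testing.assert_array_equal(vit, brute)
            assert m.log_joint(obs, vit) == pytest.approx(
                m.log_joint(obs, brute), abs=1e-9
            )

    def test_beats_random_paths(self, rng):
        m = random_model(rng, 4)
        obs = random_obs(rng, 4, 30)
        best = m.log_joint(obs, m.viterbi(obs))
        for _ in range(1000):
            path = rng.integers(1, 5, 30)
            assert m.log_joint(obs, path) <= best + 1e-12

    def test_symmetric_tie_gives_lexicographically_smallest(self, rng):
        """Identical emissions and a symmetric chain make every path
        equally likely; both decoders must return the all-ones path."""
        m = random_model(rng, 3)
        m.transmat_ = np.full((3, 3), 1 / 3)
        m.startprob_ = np.full(3, 1 / 3)
        m.means_ = np.zeros((3, 2))
        m.variances_ = np.ones((3, 2))
        m.emissionprob_ = np.full((3, 3), 1 / 3)
        obs = random_obs(rng, 3, 5)
        np.testing.assert_array_equal(m.viterbi(obs), np.ones(5))
        np.testing.assert_array_equal(m.brute_force_decode(obs), np.ones(5))

    def test_subjects_decoded_independently(self, rng):
        m = random_model(rng, 3)
        a = random_obs(rng, 3, 12)
        b = random_obs(rng, 3, 9)
        joined = Observations(
            np.vstack([a.continuous, b.continuous]),
            np.r_[a.discrete, b.discrete],
            lengths=[12, 9],
        )
        np.testing.assert_array_equal(
            m.viterbi(joined), np.r_[m.viterbi(a), m.viterbi(b)]
        )

    def test_peaked_categorical_uniform_chain_echoes_labels(self, rng):
        """If estimated labels are near-certain given the state and the
        chain is uninformative, decoding returns the labels themselves."""
        N = 3
        m = random_model(rng, N)
        m.transmat_ = np.full((N, N), 1 / N)
        m.startprob_ = np.full(N, 1 / N)
        m.means_ = np.zeros((N, 2))
        m.variances_ = np.ones((N, 2))
        m.emissionprob_ = np.full((N, N), 0.01 / (N - 1))
        np.fill_diagonal(m.emissionprob_, 0.99)
        labels = rng.integers(1, N + 1, 40)
        obs = Observations(rng.standard_normal((40, 2)) * 0, labels)
        np.testing.assert_array_equal(m.viterbi(obs), labels)

    def test_enumeration_cap(self, rng):
        m = random_model(rng, 4)
        obs = random_obs(rng, 4, 11)  # 4^11 > 1e6
        with pytest.raises(ValueError):
            m.brute_force_decode(obs)

    def test_matches_hmmlearn_gaussian_decoder(self, rng):
        """With the categorical part made uninformative, decoding must
        agree with hmmlearn's Gaussian-HMM Viterbi."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        N, T = 3, 60
        m = random_model(rng, N)
        m.emissionprob_ = np.full((N, N), 1 / N)
        obs = random_obs(rng, N, T)
        ref = hmmlearn.GaussianHMM(n_components=N, covariance_type="diag",
                                   init_params="")
        ref.startprob_ = m.startprob_
        ref.transmat_ = m.transmat_
        ref.means_ = m.means_
        ref.covars_ = m.variances_
        _, ref_path = ref.decode(obs.continuous, algorithm="viterbi")
        np.testing.assert_array_equal(m.viterbi(obs), ref_path + 1)


# ---------------------------------------------------------------- recovery


def test_transition_matrix_recovery_from_long_simulation():
    """Fitting on a long simulated sticky chain recovers A entrywise."""
    from actiseq import SyntheticConfig, build_transition_matrix, simulate_sequence

    cfg = SyntheticConfig(n_classes=4, n_features=2, n_windows=20_000,
                          stickiness=0.9, separation=2.0, seed=99)
    X, y, lengths = simulate_sequence(cfg)
    obs = Observations(X, y, lengths=lengths)
    m = SupervisedSequenceHMM(smoothing=1.0).fit(obs, y)
    A_true = build_transition_matrix(cfg)
    assert np.abs(m.transmat_ - A_true).max() < 0.02


def test_serialization_round_trip(tmp_path, rng):
    from actiseq import io as aio

    states = rng.integers(1, 4, 50)
    states[:3] = [1, 2, 3]
    obs = Observations(rng.standard_normal((50, 2)), states)
    m = SupervisedSequenceHMM(smoothing=0.5).fit(obs, states)
    aio.dump_json(tmp_path / "hmm.json", m.to_dict())
    back = SupervisedSequenceHMM.from_dict(aio.load_json(tmp_path / "hmm.json"))
    np.testing.assert_array_equal(back.transmat_, m.transmat_)
    np.testing.assert_array_equal(back.viterbi(obs), m.viterbi(obs))
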