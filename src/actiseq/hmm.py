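"""Supervised hidden Markov model over augmented observations.

The hidden state y_t is the activity performed at window t; the observation
o_t concatenates a continuous part (principal-component scores of the sensor
features) with a discrete part (the label a framewise classifier estimated
for that window).  Because activities persist over many consecutive windows,
the transition matrix is strongly diagonal and Viterbi decoding of

    P(x, y) = prod_t p(y_t | y_{t-1}) p(o_t | y_t)

smooths isolated framewise errors out of the decoded sequence.

All parameters have closed-form supervised estimates: transitions from
bigram counts of the training labels (with additive smoothing), the initial
distribution from empirical state frequencies, and per-state emissions as a
diagonal-covariance Gaussian on the continuous part times a categorical on
the discrete part, the two independent given the state.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-6


@dataclass
class Observations:
    """Aligned continuous and discrete observation streams.

    Attributes
    ----------
    continuous : ndarray (T, k)
        Principal-component scores.
    discrete : ndarray (T,)
        Estimated labels, 1-based, in 1..n_symbols.
    lengths : list[int]
        Lengths of the independent sub-sequences (one per subject);
        defaults to a single contiguous sequence.
    """

    continuous: np.ndarray
    discrete: np.ndarray
    lengths: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.continuous = np.atleast_2d(
            np.asarray(self.continuous, dtype=np.float64)
        )
        self.discrete = np.asarray(self.discrete, dtype=np.int64)
        T = self.continuous.shape[0]
        if T == 0:
            raise ValueError("empty observation sequence")
        if self.discrete.shape != (T,):
            raise ValueError("continuous and discrete parts must share length")
        if self.discrete.min() < 1:
            raise ValueError("discrete symbols are 1-based")
        if not self.lengths:
            self.lengths = [T]
        if sum(self.lengths) != T:
            raise ValueError("lengths must sum to the sequence length")

    @property
    def n_windows(self) -> int:
        return self.continuous.shape[0]

    def split(self):
        """Iterate over the independent per-subject sub-sequences."""
        start = 0
        for ln in self.lengths:
            yield Observations(
                self.continuous[start:start + ln],
                self.discrete[start:start + ln],
            )
            start += ln

    def one_hot(self, n_symbols: int) -> np.ndarray:
        """Export as a T x (k + n_symbols) matrix, discrete part one-hot."""
        eye = np.eye(n_symbols)
        return np.hstack([self.continuous, eye[self.discrete - 1]])


class SupervisedSequenceHMM(BaseEstimator):
    """HMM with factorized Gaussian x categorical emissions, fitted from
    labelled sequences and decoded with Viterbi.

    Parameters
    ----------
    smoothing : float >= 0
        Additive (Laplace) smoothing applied to transition and categorical
        emission counts.  The default 1 guards decoding against -inf scores
        from transitions unseen in training.
    variance_floor : float
        Lower bound on per-state emission variances.

    Attributes
    ----------
    n_states_ : int
    startprob_ : ndarray (N,)         empirical state frequencies
    transmat_ : ndarray (N, N)        row-stochastic transition matrix
    means_, variances_ : ndarray (N, k)
    emissionprob_ : ndarray (N, N)    categorical over estimated labels
    """

    def __init__(self, smoothing: float = 1.0,
                 variance_floor: float = VARIANCE_FLOOR):
        self.smoothing = smoothing
        self.variance_floor = variance_floor

    # -- fitting ----------------------------------------------------------
    def fit(self, obs: Observations, states):
        states = np.asarray(states, dtype=np.int64)
        if states.shape != (obs.n_windows,):
            raise ValueError("states must align with observations")
        N = int(states.max())
        present = np.unique(states)
        if len(present) != N or present.min() != 1:
            raise ValueError(
                f"every state 1..{N} must appear in the training labels"
            )
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        alpha = float(self.smoothing)

        # transitions: bigram counts, subject boundaries excluded
        trans = np.zeros((N, N))
        start = 0
        for ln in obs.lengths:
            seg = states[start:start + ln]
            for a, b in zip(seg[:-1], seg[1:]):
                trans[a - 1, b - 1] += 1
            start += ln
        num = trans + alpha
        den = num.sum(axis=1, keepdims=True)
        if (den == 0).any():
            # a state with no outgoing bigrams and zero smoothing:
            # fall back to staying put so the row remains stochastic
            stuck = den[:, 0] == 0
            num[stuck] = np.eye(N)[stuck]
            den = num.sum(axis=1, keepdims=True)
        self.transmat_ = num / den

        self.startprob_ = np.bincount(states - 1, minlength=N) / len(states)

        k = obs.continuous.shape[1]
        self.means_ = np.zeros((N, k))
        self.variances_ = np.zeros((N, k))
        emis = np.zeros((N, N))
        for s in range(1, N + 1):
            rows = obs.continuous[states == s]
            self.means_[s - 1] = rows.mean(axis=0)
            if len(rows) == 1:
                warnings.warn(
                    f"state {s} has a single observation; variance floored",
                    stacklevel=2,
                )
            var = rows.var(axis=0)
            self.variances_[s - 1] = np.maximum(var, self.variance_floor)
            emis[s - 1] = np.bincount(
                obs.discrete[states == s] - 1, minlength=N
            )
        num = emis + alpha
        self.emissionprob_ = num / num.sum(axis=1, keepdims=True)

        self.n_states_ = N
        self.n_continuous_ = k
        logger.info("fitted HMM with %d states over %d windows", N,
                    obs.n_windows)
        return self

    # -- scoring ----------------------------------------------------------
    def _emission_logprob(self, obs: Observations) -> np.ndarray:
        """T x N matrix of log b_s(o_t)."""
        check_is_fitted(self, "transmat_")
        X = obs.continuous
        if X.shape[1] != self.n_continuous_:
            raise ValueError("continuous dimension mismatch with fitted model")
        if obs.discrete.max() > self.n_states_:
            raise ValueError("discrete symbol out of range")
        var = self.variances_[None, :, :]  # 1 x N x k
        diff = X[:, None, :] - self.means_[None, :, :]
        log_gauss = -0.5 * np.sum(
            np.log(2.0 * np.pi * var) + diff**2 / var, axis=2
        )
        with np.errstate(divide="ignore"):
            log_cat = np.log(self.emissionprob_)[:, obs.discrete - 1].T
        return log_gauss + log_cat

    def log_joint(self, obs: Observations, states) -> float:
        """log P(x, y) for a given state path (Markov factorization).

        Returns -inf (not an error) if the path uses a zero-probability
        transition under smoothing 0.
        """
        states = np.asarray(states, dtype=np.int64)
        if states.shape != (obs.n_windows,):
            raise ValueError("states must align with observations")
        if states.min() < 1 or states.max() > self.n_states_:
            raise ValueError("state out of range")
        logB = self._emission_logprob(obs)
        with np.errstate(divide="ignore"):
            logA = np.log(self.transmat_)
            logpi = np.log(self.startprob_)
        total = 0.0
        start = 0
        for ln in obs.lengths:
            seg = states[start:start + ln] - 1
            total += logpi[seg[0]]
            total += logA[seg[:-1], seg[1:]].sum()
            total += logB[np.arange(start, start + ln), seg].sum()
            start += ln
        return float(total)

    # -- decoding ---------------------------------------------------------
    def viterbi(self, obs: Observations) -> np.ndarray:
        """Most probable state path, decoded per subject in log space.

        Ties in the dynamic program are broken toward the smaller state
        index at every backtrack step.
        """
        check_is_fitted(self, "transmat_")
        with np.errstate(divide="ignore"):
            logA = np.log(self.transmat_)
            logpi = np.log(self.startprob_)
        out = []
        for seg in obs.split():
            logB = self._emission_logprob(seg)
            T = seg.n_windows
            N = self.n_states_
            delta = np.zeros((T, N))
            psi = np.zeros((T, N), dtype=np.int64)
            delta[0] = logpi + logB[0]
            for t in range(1, T):
                cand = delta[t - 1][:, None] + logA  # prev x next
                psi[t] = np.argmax(cand, axis=0)  # first max: smaller index
                delta[t] = cand[psi[t], np.arange(N)] + logB[t]
            path = np.zeros(T, dtype=np.int64)
            path[-1] = np.argmax(delta[-1])
            for t in range(T - 2, -1, -1):
                path[t] = psi[t + 1][path[t + 1]]
            out.append(path + 1)
        return np.concatenate(out)

    def brute_force_decode(self, obs: Observations) -> np.ndarray:
        """Exhaustive-enumeration decoder (test oracle).

        Enumerates all N^T paths per subject in lexicographic order and
        keeps the first maximizer, so exact ties resolve to the
        lexicographically smallest optimal path.
        """
        check_is_fitted(self, "transmat_")
        N = self.n_states_
        with np.errstate(divide="ignore"):
            logA = np.log(self.transmat_)
            logpi = np.log(self.startprob_)
        out = []
        for seg in obs.split():
            T = seg.n_windows
            if N**T > 10**6:
                raise ValueError(
                    f"{N}^{T} paths exceed the enumeration cap"
                )
            logB = self._emission_logprob(seg)
            # all N^T paths, rows in lexicographic order
            paths = np.stack(
                np.unravel_index(np.arange(N**T), (N,) * T), axis=1
            )
            scores = logpi[paths[:, 0]] + logB[np.arange(T), paths].sum(axis=1)
            if T > 1:
                scores += logA[paths[:, :-1], paths[:, 1:]].sum(axis=1)
            # first argmax = lexicographically smallest maximizer
            out.append(paths[np.argmax(scores)] + 1)
        return np.concatenate(out)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        check_is_fitted(self, "transmat_")
        return {
            "smoothing": self.smoothing,
            "variance_floor": self.variance_floor,
            "startprob": self.startprob_,
            "transmat": self.transmat_,
            "means": self.means_,
            "variances": self.variances_,
            "emissionprob": self.emissionprob_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SupervisedSequenceHMM":
        model = cls(smoothing=float(d["smoothing"]),
                    variance_floor=float(d["variance_floor"]))
        model.startprob_ = np.asarray(d["startprob"], dtype=np.float64)
        model.transmat_ = np.asarray(d["transmat"], dtype=np.float64)
        model.means_ = np.asarray(d["means"], dtype=np.float64)
        model.variances_ = np.asarray(d["variances"], dtype=np.float64)
        model.emissionprob_ = np.asarray(d["emissionprob"], dtype=np.float64)
        model.n_states_ = model.transmat_.shape[0]
        model.n_continuous_ = model.means_.shape[1]
        return model
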