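"""Synthetic activity-like sequence generator.

Emulates the structure wearable-sensor activity streams exhibit: activities
persist over many consecutive windows (a sticky first-order Markov chain),
each activity produces feature windows from its own class-conditional
distribution (spherical Gaussians around class means), and class frequencies
are imbalanced.  Imbalance is induced through the chain's stationary
distribution rather than post-hoc subsampling, so the transition structure
stays realistic.

Two knobs matter for experiments: `stickiness` (self-transition probability,
driving how much temporal smoothing can help) and `separation` (distance
between class means in units of the emission standard deviation, driving the
framewise Bayes error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Attributes
    ----------
    n_classes : int
        Number of activities N.
    n_features : int
        Feature dimension p; class means are scaled coordinate-like unit
        directions so p >= n_classes gives mutually orthogonal means.
    n_windows : int
        Sequence length T per subject.
    n_subjects : int
        Number of independent sequences.
    stickiness : float in [0, 1)
        Self-transition probability s; off-diagonal mass is distributed
        proportionally to `weights`.
    separation : float
        Distance scale d between class means, in emission-sd units.
    variance : float
        Isotropic emission variance per feature.
    weights : sequence of float or None
        Length-N positive weights biasing the chain's stationary
        distribution (None = uniform).
    seed : int
    """

    n_classes: int = 4
    n_features: int = 6
    n_windows: int = 500
    n_subjects: int = 1
    stickiness: float = 0.95
    separation: float = 3.0
    variance: float = 1.0
    weights: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.stickiness < 1:
            raise ValueError("stickiness must be in [0, 1)")
        if self.separation <= 0 or self.variance <= 0:
            raise ValueError("separation and variance must be positive")
        if self.n_classes < 1 or self.n_features < 1 or self.n_windows < 1:
            raise ValueError("n_classes, n_features, n_windows must be >= 1")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=np.float64)
            if w.shape != (self.n_classes,) or (w <= 0).any():
                raise ValueError("weights must be length-N and positive")

    @property
    def normalized_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        w = np.asarray(self.weights, dtype=np.float64)
        return w / w.sum()

    @property
    def class_means(self) -> np.ndarray:
        """N x p means: scaled unit directions cycling over axes."""
        means = np.zeros((self.n_classes, self.n_features))
        for c in range(self.n_classes):
            means[c, c % self.n_features] = self.separation * (
                1 + c // self.n_features
            )
        return means


def build_transition_matrix(cfg: SyntheticConfig) -> np.ndarray:
    """A = s I + (1 - s) 1 w^T with w the normalized imbalance weights."""
    w = cfg.normalized_weights
    A = cfg.stickiness * np.eye(cfg.n_classes) + (
        1.0 - cfg.stickiness
    ) * np.tile(w, (cfg.n_classes, 1))
    return A


def stationary_distribution(A: np.ndarray) -> np.ndarray:
    """Left eigenvector of A for eigenvalue 1, normalized to a distribution."""
    evals, evecs = np.linalg.eig(A.T)
    idx = np.argmin(np.abs(evals - 1.0))
    pi = np.real(evecs[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def simulate_sequence(cfg: SyntheticConfig):
    """Draw (features, labels, lengths) from the configured model.

    Returns
    -------
    X : ndarray (n_subjects * n_windows, n_features)
    y : ndarray of 1-based labels, same length
    lengths : list[int], n_windows per subject
    """
    rng = np.random.default_rng(cfg.seed)
    A = build_transition_matrix(cfg)
    w = cfg.normalized_weights
    means = cfg.class_means
    sd = np.sqrt(cfg.variance)
    Xs, ys, lengths = [], [], []
    for _ in range(cfg.n_subjects):
        states = np.zeros(cfg.n_windows, dtype=np.int64)
        states[0] = rng.choice(cfg.n_classes, p=w)
        for t in range(1, cfg.n_windows):
            states[t] = rng.choice(cfg.n_classes, p=A[states[t - 1]])
        X = means[states] + sd * rng.standard_normal(
            (cfg.n_windows, cfg.n_features)
        )
        Xs.append(X)
        ys.append(states + 1)
        lengths.append(cfg.n_windows)
    return np.vstack(Xs), np.concatenate(ys), lengths
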