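"""PCA by eigendecomposition of the feature scatter matrix.

The covariance structure is summarised by the unnormalised scatter matrix

    S = sum_j (x_j - mu)(x_j - mu)^T

whose eigenvectors coincide with those of the sample covariance (the 1/(T-1)
factor rescales eigenvalues only).  Windows of wearable-sensor features are
highly collinear (hundreds of correlated statistics of the same few signals),
so a small number of leading components captures nearly all variance.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


class ScatterPCA(TransformerMixin, BaseEstimator):
    """Principal component analysis via the scatter-matrix eigenproblem.

    Solves ``lambda V = S V`` with ``||v_i|| = 1`` for the scatter matrix S
    defined above, and projects data onto the leading eigenvectors.

    Parameters
    ----------
    n_components : int or None
        Number of components kept by :meth:`transform` when not given
        explicitly.  If None, chosen at fit time as the smallest k whose
        cumulative explained-variance fraction reaches `variance_fraction`.
    variance_fraction : float in (0, 1]
        Target cumulative explained-variance fraction used when
        `n_components` is None.

    Attributes
    ----------
    mean_ : ndarray (p,)
        Column means mu.
    components_ : ndarray (p, p)
        Orthonormal eigenvectors of S, one per *column*, sorted by
        descending eigenvalue.  Sign convention: the largest-magnitude entry
        of each eigenvector is positive.
    eigenvalues_ : ndarray (p,)
        Eigenvalues of S, descending, clipped tiny negatives to 0.
    n_components_ : int
        The retained k.
    """

    def __init__(self, n_components: int | None = None,
                 variance_fraction: float = 0.95):
        self.n_components = n_components
        self.variance_fraction = variance_fraction

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2, dtype=np.float64)
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        S = Xc.T @ Xc  # scatter matrix, no 1/(T-1)
        evals, evecs = np.linalg.eigh(S)
        order = np.argsort(evals, kind="stable")[::-1]
        evals = evals[order]
        evecs = evecs[:, order]
        # deterministic signs: largest-magnitude entry of each column positive
        for i in range(evecs.shape[1]):
            j = np.argmax(np.abs(evecs[:, i]))
            if evecs[j, i] < 0:
                evecs[:, i] = -evecs[:, i]
        if evals.min() < -1e-8 * max(1.0, abs(evals.max())):
            raise np.linalg.LinAlgError("scatter matrix not PSD")
        self.eigenvalues_ = np.clip(evals, 0.0, None)
        self.components_ = evecs
        self.n_features_in_ = X.shape[1]
        if self.n_components is not None:
            k = int(self.n_components)
            if not 1 <= k <= self.n_features_in_:
                raise ValueError(f"n_components={k} out of range [1, {self.n_features_in_}]")
            self.n_components_ = k
        else:
            self.n_components_ = self.choose_k(self.variance_fraction)
        return self

    def choose_k(self, variance_fraction: float) -> int:
        """Smallest k with cumulative explained variance >= the fraction."""
        check_is_fitted(self, "eigenvalues_")
        if not 0.0 < variance_fraction <= 1.0:
            raise ValueError("variance_fraction must be in (0, 1]")
        total = self.eigenvalues_.sum()
        if total == 0:
            return 1
        frac = np.cumsum(self.eigenvalues_) / total
        # tolerate rounding at fraction 1.0: count strictly positive eigenvalues
        if variance_fraction >= 1.0:
            return max(1, int((self.eigenvalues_ > 0).sum()))
        return int(np.searchsorted(frac, variance_fraction) + 1)

    def transform(self, X, n_components: int | None = None):
        """Project onto the first k eigenvectors: ``(X - mu) V[:, :k]``."""
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature-count mismatch with fitted model")
        k = self.n_components_ if n_components is None else int(n_components)
        if not 1 <= k <= self.n_features_in_:
            raise ValueError(f"k={k} out of range [1, {self.n_features_in_}]")
        return (X - self.mean_) @ self.components_[:, :k]

    def to_dict(self) -> dict:
        check_is_fitted(self, "components_")
        return {
            "mean": self.mean_,
            "components": self.components_,
            "eigenvalues": self.eigenvalues_,
            "n_components": self.n_components_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScatterPCA":
        model = cls(n_components=int(d["n_components"]))
        model.mean_ = np.asarray(d["mean"], dtype=np.float64)
        model.components_ = np.asarray(d["components"], dtype=np.float64)
        model.eigenvalues_ = np.asarray(d["eigenvalues"], dtype=np.float64)
        model.n_components_ = int(d["n_components"])
        model.n_features_in_ = model.components_.shape[0]
        return model
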