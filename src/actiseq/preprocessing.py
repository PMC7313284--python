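"""Per-feature range scaling to [-1, 1].

Activity-recognition feature tables mix channels on very different scales
(body-acceleration means near zero, signal magnitudes in the hundreds), so
features are affinely mapped into [-1, 1] using extrema estimated on the
training split before any kernel computation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted


class RangeScaler(TransformerMixin, BaseEstimator):
    """Map each feature affinely onto [-1, 1] using training extrema.

    For a feature with training minimum ``lo`` and maximum ``hi`` the map is
    ``x' = 2 (x - lo) / (hi - lo) - 1``.  Unlike clipping scalers, values seen
    at transform time outside the training range are mapped by the same affine
    rule and may fall outside [-1, 1]; clipping would distort kernel distances
    between test points.  Constant training features map to 0 (the midpoint).

    Attributes
    ----------
    data_min_, data_max_ : ndarray of shape (n_features,)
        Per-feature training extrema.
    n_features_in_ : int
    """

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1, dtype=np.float64)
        self.data_min_ = X.min(axis=0)
        self.data_max_ = X.max(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "data_min_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, scaler was fitted with "
                f"{self.n_features_in_}"
            )
        span = self.data_max_ - self.data_min_
        out = np.zeros_like(X)
        nz = span > 0
        out[:, nz] = 2.0 * (X[:, nz] - self.data_min_[nz]) / span[nz] - 1.0
        return out
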