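"""Class-cost-weighted SVM with a Gaussian kernel.

Activity classes are imbalanced (postures such as lying dominate sequences,
transitions are rare), and a plain soft-margin SVM pushes its boundary into
the minority class.  The weighted SVM counters this with a different
misclassification penalty per class: each class i receives the box bound

    C_i = round(C * m_plus / m_i),   floored at 1,

where m_i is the class-i training count and m_plus the largest class count,
so errors on small classes cost proportionally more.  The binary subproblems
solve the usual soft-margin dual

    max  sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j)
    s.t. 0 <= a_i <= C_{class(i)},   sum_i a_i y_i = 0,

with K the Gaussian kernel exp(-||x - y||^2 / (2 sigma^2)), by sequential
minimal optimization (SMO) with second-order working-set selection.
Multiclass extension is one-vs-one with majority voting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import LeaveOneOut, StratifiedKFold
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import ConvergenceError

#: hyperparameter grids used for cross-validated model selection
DEFAULT_SIGMA_GRID = (0.1, 0.2, 0.5, 1.0)
DEFAULT_C_GRID = (0.1, 1.0, 5.0, 10.0, 100.0)


def gaussian_kernel(x, y, sigma: float):
    """K(x, y) = exp(-||x - y||^2 / (2 sigma^2)) for single vectors."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal dimension")
    d2 = np.sum((x - y) ** 2)
    return float(np.exp(-d2 / (2.0 * sigma**2)))


def _kernel_matrix(X, Y, sigma: float) -> np.ndarray:
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return rbf_kernel(X, Y, gamma=1.0 / (2.0 * sigma**2))


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class CostScheme:
    """Per-class box bounds derived from the majority-to-class count ratio."""

    base_cost: float
    counts: np.ndarray  # class counts m_i, index 0 <-> class 1
    costs: np.ndarray = field(init=False)  # integer C_i, same indexing

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or len(counts) == 0:
            raise ValueError("counts must be a non-empty vector")
        if (counts < 1).any():
            raise ValueError("every class must have at least one sample")
        object.__setattr__(self, "counts", counts)
        m_plus = counts.max()
        raw = _round_half_away(self.base_cost * m_plus / counts)
        object.__setattr__(
            self, "costs", np.maximum(raw, 1.0).astype(np.int64)
        )

    def cost_of(self, cls: int) -> int:
        """Box bound for 1-based class index `cls`."""
        return int(self.costs[cls - 1])


def class_costs(counts, C: float) -> CostScheme:
    """Eq.-style cost scheme: C_i = round(C * m_plus / m_i), floored at 1.

    Rounding is half away from zero (2.5 -> 3).
    """
    return CostScheme(base_cost=float(C), counts=np.asarray(counts))


def _smo_solve(K, y, upper, tol=1e-3, max_iter=100_000):
    """Minimize 1/2 a'Qa - e'a  s.t. 0 <= a_i <= upper_i, y'a = 0.

    Q = (y y') * K.  Second-order working-set selection (the pair
    maximally violating the KKT conditions, second choice by decrease of the
    objective), deterministic ties to the smallest index.  Returns
    (alpha, b, n_iter).
    """
    n = len(y)
    y = np.asarray(y, dtype=np.float64)
    upper = np.asarray(upper, dtype=np.float64)
    Kd = np.diag(K).copy()
    alpha = np.zeros(n)
    grad = -np.ones(n)  # gradient of the dual objective at alpha = 0
    tau = 1e-12
    # snap alphas sitting within rounding error of a bound exactly onto it,
    # so the working-set masks exclude them instead of cycling on ULP steps
    snap = 1e-10 * np.maximum(upper, 1.0)

    for it in range(max_iter):
        yg = -y * grad  # equals y_k - g_k where g is the raw decision value
        up_mask = ((y > 0) & (alpha < upper)) | ((y < 0) & (alpha > 0))
        low_mask = ((y < 0) & (alpha < upper)) | ((y > 0) & (alpha > 0))
        if not up_mask.any() or not low_mask.any():
            b = 0.0 if not up_mask.any() and not low_mask.any() else float(
                yg[up_mask | low_mask].mean()
            )
            return alpha, b, it
        m_val = np.max(yg[up_mask])
        i = int(np.argmax(np.where(up_mask, yg, -np.inf)))
        M_val = np.min(yg[low_mask])
        if m_val - M_val <= tol:
            break
        # second-order choice of j: largest guaranteed objective decrease
        cand = low_mask & (yg < m_val)
        if not cand.any():
            break
        bvec = m_val - yg
        avec = np.maximum(Kd[i] + Kd - 2.0 * K[i], tau)
        score = np.where(cand, -(bvec * bvec) / avec, np.inf)
        j = int(np.argmin(score))

        # analytic two-variable update along y_i a_i + y_j a_j = const
        s = y[i] * y[j]
        if s < 0:
            L = max(0.0, alpha[j] - alpha[i])
            H = min(upper[j], upper[i] + alpha[j] - alpha[i])
        else:
            L = max(0.0, alpha[i] + alpha[j] - upper[i])
            H = min(upper[j], alpha[i] + alpha[j])
        eta = max(Kd[i] + Kd[j] - 2.0 * K[i, j], tau)
        E_i = y[i] * grad[i]
        E_j = y[j] * grad[j]
        aj_new = np.clip(alpha[j] + y[j] * (E_i - E_j) / eta, L, H)
        d_j = aj_new - alpha[j]
        if d_j == 0.0:
            break  # numerically stuck; gap reported below
        d_i = -s * d_j
        alpha[i] += d_i
        alpha[j] = aj_new
        grad += (K[i] * y) * (y[i] * d_i) + (K[j] * y) * (y[j] * d_j)
        for idx in (i, j):
            if alpha[idx] < snap[idx]:
                alpha[idx] = 0.0
            elif alpha[idx] > upper[idx] - snap[idx]:
                alpha[idx] = upper[idx]
    else:
        raise ConvergenceError(
            f"SMO did not converge within {max_iter} iterations",
            gap=float(m_val - M_val),
        )

    free = (alpha > 1e-8 * upper) & (alpha < upper * (1 - 1e-8))
    if free.any():
        b = float(yg[free].mean())
    else:
        b = float((m_val + M_val) / 2.0)
    return alpha, b, it


class BinaryWeightedSVC(BaseEstimator):
    """Two-class Gaussian-kernel SVM with separate box bounds per class.

    Labels must be in {-1, +1}; samples with y=+1 are bounded by `C_pos`,
    samples with y=-1 by `C_neg`.
    """

    def __init__(self, C_pos: float = 1.0, C_neg: float = 1.0,
                 sigma: float = 1.0, tol: float = 1e-3,
                 max_iter: int = 100_000):
        self.C_pos = C_pos
        self.C_neg = C_neg
        self.sigma = sigma
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if not np.all(np.isin(y, (-1.0, 1.0))):
            raise ValueError("labels must be -1 or +1")
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        upper = np.where(y > 0, float(self.C_pos), float(self.C_neg))
        K = _kernel_matrix(X, X, self.sigma)
        alpha, b, n_iter = _smo_solve(
            K, y, upper, tol=self.tol, max_iter=self.max_iter
        )
        sv = alpha > 1e-12
        if not sv.any():  # pragma: no cover - SMO always moves off zero
            raise RuntimeError("no support vectors after training")
        self.alpha_ = alpha[sv]
        self.support_ = np.flatnonzero(sv)
        self.support_vectors_ = X[sv]
        self.sv_labels_ = y[sv]
        self.dual_coef_ = self.alpha_ * self.sv_labels_
        self.intercept_ = b
        self.n_iter_ = n_iter
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        """Pre-sign decision value  sum_i a_i y_i K(x, x_i) + b."""
        check_is_fitted(self, "alpha_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature-count mismatch with fitted model")
        K = _kernel_matrix(X, self.support_vectors_, self.sigma)
        return K @ self.dual_coef_ + self.intercept_

    def predict(self, X):
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def to_dict(self) -> dict:
        check_is_fitted(self, "alpha_")
        return {
            "C_pos": self.C_pos,
            "C_neg": self.C_neg,
            "sigma": self.sigma,
            "support_vectors": self.support_vectors_,
            "alpha": self.alpha_,
            "sv_labels": self.sv_labels_,
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BinaryWeightedSVC":
        model = cls(C_pos=float(d["C_pos"]), C_neg=float(d["C_neg"]),
                    sigma=float(d["sigma"]))
        model.support_vectors_ = np.asarray(d["support_vectors"],
                                            dtype=np.float64)
        model.alpha_ = np.asarray(d["alpha"], dtype=np.float64)
        model.sv_labels_ = np.asarray(d["sv_labels"], dtype=np.float64)
        model.dual_coef_ = model.alpha_ * model.sv_labels_
        model.intercept_ = float(d["intercept"])
        model.n_features_in_ = model.support_vectors_.shape[1]
        return model


class WeightedSVC(ClassifierMixin, BaseEstimator):
    """One-vs-one multiclass weighted SVM.

    At fit time the per-class cost scheme is computed from the training
    counts; each of the N(N-1)/2 binary machines is trained on its two
    classes with their respective bounds.  Prediction is majority voting,
    ties broken toward the smallest class index.

    Parameters
    ----------
    C : float
        Base cost in the per-class scheme.
    sigma : float
        Gaussian kernel width.
    weighted : bool
        If False, every class uses the raw cost C (unweighted reference
        behaviour, used for comparisons).
    """

    def __init__(self, C: float = 10.0, sigma: float = 1.0,
                 weighted: bool = True, tol: float = 1e-3,
                 max_iter: int = 100_000):
        self.C = C
        self.sigma = sigma
        self.weighted = weighted
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        if classes.min() < 1:
            raise ValueError("labels are 1-based")
        self.classes_ = classes
        counts = np.array([(y == c).sum() for c in classes])
        if self.weighted:
            scheme = CostScheme(base_cost=float(self.C), counts=counts)
            bounds = {int(c): float(scheme.costs[k])
                      for k, c in enumerate(classes)}
        else:
            scheme = None
            bounds = {int(c): float(self.C) for c in classes}
        self.cost_scheme_ = scheme
        self.machines_ = {}
        for a_idx in range(len(classes)):
            for b_idx in range(a_idx + 1, len(classes)):
                ca, cb = int(classes[a_idx]), int(classes[b_idx])
                mask = (y == ca) | (y == cb)
                y_signed = np.where(y[mask] == ca, 1.0, -1.0)
                machine = BinaryWeightedSVC(
                    C_pos=bounds[ca], C_neg=bounds[cb], sigma=self.sigma,
                    tol=self.tol, max_iter=self.max_iter,
                ).fit(X[mask], y_signed)
                self.machines_[(ca, cb)] = machine
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "machines_")
        X = check_array(X, dtype=np.float64)
        votes = np.zeros((X.shape[0], len(self.classes_)), dtype=np.int64)
        cls_index = {int(c): k for k, c in enumerate(self.classes_)}
        for (ca, cb), machine in self.machines_.items():
            dec = machine.decision_function(X)
            votes[dec >= 0, cls_index[ca]] += 1
            votes[dec < 0, cls_index[cb]] += 1
        # argmax returns the first maximum: smallest class index wins ties
        return self.classes_[np.argmax(votes, axis=1)]

    def to_dict(self) -> dict:
        check_is_fitted(self, "machines_")
        return {
            "C": self.C,
            "sigma": self.sigma,
            "weighted": self.weighted,
            "classes": self.classes_,
            "class_counts": (
                self.cost_scheme_.counts if self.cost_scheme_ is not None
                else None
            ),
            "machines": {
                f"{ca}-{cb}": machine.to_dict()
                for (ca, cb), machine in sorted(self.machines_.items())
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WeightedSVC":
        model = cls(C=float(d["C"]), sigma=float(d["sigma"]),
                    weighted=bool(d["weighted"]))
        model.classes_ = np.asarray(d["classes"], dtype=np.int64)
        model.cost_scheme_ = (
            CostScheme(base_cost=float(d["C"]),
                       counts=np.asarray(d["class_counts"]))
            if d.get("class_counts") is not None else None
        )
        model.machines_ = {}
        for key, sub in d["machines"].items():
            ca, cb = (int(v) for v in key.split("-"))
            model.machines_[(ca, cb)] = BinaryWeightedSVC.from_dict(sub)
        first = next(iter(model.machines_.values()))
        model.n_features_in_ = first.n_features_in_
        return model


def _folds(y, n_folds: int, seed: int):
    """Stratified fold iterator; n_folds == n_samples means leave-one-out."""
    y = np.asarray(y)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds == len(y):
        return LeaveOneOut().split(np.zeros(len(y)), y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(
            f"cannot stratify: smallest class has {counts.min()} samples "
            f"for {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return skf.split(np.zeros(len(y)), y)


def cv_label_estimate(X, y, sigma: float, C: float, folds: int = 5,
                      seed: int = 0, weighted: bool = True) -> np.ndarray:
    """Out-of-fold label estimates.

    Every row receives exactly one prediction, from a model whose training
    excluded that row's fold; the cost scheme is recomputed per fold from
    the fold-train counts.  These estimates carry the label-error statistics
    a downstream model will actually see at test time.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    out = np.zeros(len(y), dtype=np.int64)
    for train_idx, test_idx in _folds(y, folds, seed):
        model = WeightedSVC(C=C, sigma=sigma, weighted=weighted)
        model.fit(X[train_idx], y[train_idx])
        out[test_idx] = model.predict(X[test_idx])
    return out


def grid_search(X, y, sigma_grid=DEFAULT_SIGMA_GRID, C_grid=DEFAULT_C_GRID,
                folds: int = 5, seed: int = 0, weighted: bool = True):
    """Cross-validated (sigma, C) selection by out-of-fold accuracy.

    Returns ``(sigma_opt, C_opt, table)`` where `table` is a DataFrame with
    one row per (sigma, C) candidate and its CV accuracy in [0, 1].  Ties
    are broken toward smaller C, then smaller sigma.
    """
    sigma_grid = list(sigma_grid)
    C_grid = list(C_grid)
    if not sigma_grid or not C_grid:
        raise ValueError("grids must be non-empty")
    y = np.asarray(y, dtype=np.int64)
    rows = []
    best = None
    for C in sorted(C_grid):
        for sigma in sorted(sigma_grid):
            est = cv_label_estimate(
                X, y, sigma=sigma, C=C, folds=folds, seed=seed,
                weighted=weighted,
            )
            acc = float(np.mean(est == y))
            rows.append({"sigma": sigma, "C": C, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, sigma, C)
    table = pd.DataFrame(rows)
    return best[1], best[2], table
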