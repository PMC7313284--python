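"""Hybrid weighted-SVM / HMM activity classifier.

Training pipeline:

1. scale features to [-1, 1] (extrema from the training split);
2. reduce dimension with scatter-matrix PCA;
3. grid-search the kernel width sigma and base cost C by stratified
   cross-validation on the component scores;
4. train the final one-vs-one weighted SVM with per-class costs from the
   full training counts;
5. re-run cross-validation at the selected (sigma, C) to obtain an
   *out-of-fold* estimated label for every training window — predictions
   from models that never saw the window — so the estimates carry the
   label-error statistics the HMM will face on test data;
6. fit the supervised HMM on the component scores concatenated with those
   estimated labels, with the true activities as hidden states.

Prediction normalizes and projects with the training transforms, lets the
final weighted SVM label each window, and Viterbi-decodes the augmented
observation stream; the decoded hidden states are the recognized activities.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_is_fitted

from . import io as aio
from .decomposition import ScatterPCA
from .hmm import Observations, SupervisedSequenceHMM
from .preprocessing import RangeScaler
from .svm import (
    DEFAULT_C_GRID,
    DEFAULT_SIGMA_GRID,
    WeightedSVC,
    cv_label_estimate,
    grid_search,
)

logger = logging.getLogger(__name__)


def augment(scores, est_labels, n_classes: int, lengths=None) -> Observations:
    """Concatenate component scores with estimated labels into the HMM's
    observation stream (continuous part + categorical part)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    est_labels = np.asarray(est_labels, dtype=np.int64)
    if scores.shape[0] == 0:
        raise ValueError("empty sequence")
    if est_labels.shape != (scores.shape[0],):
        raise ValueError("scores and labels must share length")
    if est_labels.min() < 1 or est_labels.max() > n_classes:
        raise ValueError(f"labels must lie in 1..{n_classes}")
    return Observations(scores, est_labels,
                        lengths=list(lengths) if lengths else [])


class HybridWSVMHMM(ClassifierMixin, BaseEstimator):
    """Temporally-smoothed activity classifier (weighted SVM + HMM).

    Parameters
    ----------
    n_components : int or None
        Retained principal components; None selects the smallest number
        reaching `variance_fraction` cumulative explained variance.
    variance_fraction : float
    sigma_grid, C_grid : sequences
        Hyperparameter candidates for the weighted SVM.
    folds : int
        Stratified CV folds for both grid search and out-of-fold label
        estimation.
    smoothing : float
        Additive smoothing of HMM transition/categorical counts.
    random_state : int
        Seed controlling fold assignment (the only stochastic step).

    Attributes
    ----------
    scaler_, pca_, svc_, hmm_ : fitted pipeline stages
    sigma_, C_ : selected hyperparameters
    cv_table_ : DataFrame of CV accuracies per (sigma, C)
    report_ : dict summarizing the fitted configuration
    """

    def __init__(self, n_components: int | None = None,
                 variance_fraction: float = 0.95,
                 sigma_grid=DEFAULT_SIGMA_GRID, C_grid=DEFAULT_C_GRID,
                 folds: int = 5, smoothing: float = 1.0,
                 random_state: int = 0):
        self.n_components = n_components
        self.variance_fraction = variance_fraction
        self.sigma_grid = sigma_grid
        self.C_grid = C_grid
        self.folds = folds
        self.smoothing = smoothing
        self.random_state = random_state

    def fit(self, X, y, lengths=None):
        X, y = check_X_y(X, y, dtype=np.float64)
        y = np.asarray(y, dtype=np.int64)
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

        logger.info("stage 1/6: range scaling (%d windows, %d features)",
                    *X.shape)
        self.scaler_ = RangeScaler().fit(X)
        Xn = self.scaler_.transform(X)

        logger.info("stage 2/6: PCA")
        self.pca_ = ScatterPCA(
            n_components=self.n_components,
            variance_fraction=self.variance_fraction,
        ).fit(Xn)
        Z = self.pca_.transform(Xn)
        logger.info("retained %d/%d components", self.pca_.n_components_,
                    Xn.shape[1])

        logger.info("stage 3/6: grid search over %d x %d candidates",
                    len(list(self.sigma_grid)), len(list(self.C_grid)))
        self.sigma_, self.C_, self.cv_table_ = grid_search(
            Z, y, sigma_grid=self.sigma_grid, C_grid=self.C_grid,
            folds=self.folds, seed=self.random_state,
        )
        logger.info("selected sigma=%g C=%g", self.sigma_, self.C_)

        logger.info("stage 4/6: final weighted SVM")
        self.svc_ = WeightedSVC(C=self.C_, sigma=self.sigma_).fit(Z, y)

        logger.info("stage 5/6: out-of-fold label estimation")
        est = cv_label_estimate(
            Z, y, sigma=self.sigma_, C=self.C_, folds=self.folds,
            seed=self.random_state,
        )

        logger.info("stage 6/6: supervised HMM")
        n_classes = int(self.svc_.classes_.max())
        obs = augment(Z, est, n_classes, lengths=lengths)
        self.hmm_ = SupervisedSequenceHMM(smoothing=self.smoothing).fit(obs, y)

        self.classes_ = self.svc_.classes_
        self.oof_labels_ = est
        self.report_ = {
            "n_components": int(self.pca_.n_components_),
            "sigma": float(self.sigma_),
            "C": float(self.C_),
            "class_costs": self.svc_.cost_scheme_.costs.tolist(),
            "n_binary_machines": len(self.svc_.machines_),
            "oof_accuracy": float(np.mean(est == y)),
            "cv_table": self.cv_table_.to_dict(orient="records"),
        }
        return self

    def _project(self, X):
        check_is_fitted(self, "hmm_")
        return self.pca_.transform(self.scaler_.transform(X))

    def predict_framewise(self, X):
        """Labels from the weighted SVM alone (no temporal smoothing)."""
        return self.svc_.predict(self._project(X))

    def predict(self, X, lengths=None):
        """Viterbi-decoded activity labels for a time-ordered window stream."""
        Z = self._project(X)
        est = self.svc_.predict(Z)
        obs = augment(Z, est, int(self.classes_.max()), lengths=lengths)
        return self.hmm_.viterbi(obs)

    # -- bundle I/O -------------------------------------------------------
    def save_bundle(self, directory):
        """Write the fitted model as a directory of JSON files."""
        check_is_fitted(self, "hmm_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        aio.dump_json(directory / "scaler.json", {
            "data_min": self.scaler_.data_min_,
            "data_max": self.scaler_.data_max_,
        })
        aio.dump_json(directory / "pca.json", self.pca_.to_dict())
        aio.dump_json(directory / "wsvm.json", self.svc_.to_dict())
        aio.dump_json(directory / "hmm.json", self.hmm_.to_dict())
        aio.dump_json(directory / "config.json", {
            "sigma": self.sigma_,
            "C": self.C_,
            "folds": self.folds,
            "smoothing": self.smoothing,
            "random_state": self.random_state,
            "classes": self.classes_,
            "report": self.report_,
        })

    @classmethod
    def load_bundle(cls, directory) -> "HybridWSVMHMM":
        directory = Path(directory)
        cfg = aio.load_json(directory / "config.json")
        model = cls(folds=int(cfg["folds"]), smoothing=float(cfg["smoothing"]),
                    random_state=int(cfg["random_state"]))
        sc = aio.load_json(directory / "scaler.json")
        scaler = RangeScaler()
        scaler.data_min_ = np.asarray(sc["data_min"], dtype=np.float64)
        scaler.data_max_ = np.asarray(sc["data_max"], dtype=np.float64)
        scaler.n_features_in_ = len(scaler.data_min_)
        model.scaler_ = scaler
        model.pca_ = ScatterPCA.from_dict(aio.load_json(directory / "pca.json"))
        model.svc_ = WeightedSVC.from_dict(aio.load_json(directory / "wsvm.json"))
        model.hmm_ = SupervisedSequenceHMM.from_dict(
            aio.load_json(directory / "hmm.json"))
        model.sigma_ = float(cfg["sigma"])
        model.C_ = float(cfg["C"])
        model.classes_ = np.asarray(cfg["classes"], dtype=np.int64)
        model.report_ = cfg["report"]
        return model
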