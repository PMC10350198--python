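"""Combining CNN and SVM information.

Three routes: (i) a weighted average of the two models' class probabilities
swept over a weight grid (weight 1 = CNN only, 0 = SVM only); (ii) stacking
with a linear discriminant meta-learner fit on inner-fold out-of-sample
probabilities; (iii) SVMs trained directly on CNN-derived features (latent
activations or saliency maps), generated for each subject by the fold model
under which that subject was held out.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import AlignmentError, CoverageError
from .evaluation import confusion_metrics

log = logging.getLogger(__name__)

DEFAULT_WEIGHT_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


def weighted_average_ensemble(
    p_cnn: np.ndarray, p_svm: np.ndarray, y_true: np.ndarray,
    weight_grid=DEFAULT_WEIGHT_GRID,
) -> dict:
    """F1 curve of the probability-averaging ensemble over the weight grid."""
    p_cnn, p_svm = np.asarray(p_cnn), np.asarray(p_svm)
    if p_cnn.shape != p_svm.shape or len(p_cnn) != len(y_true):
        raise AlignmentError("probability arrays must align subject-for-subject")
    weights = np.asarray(weight_grid, dtype=np.float64)
    if weights.min() < 0 or weights.max() > 1:
        raise AlignmentError("weights must lie in [0, 1]")
    f1s, preds = [], {}
    for w in weights:
        p = w * p_cnn + (1.0 - w) * p_svm
        yhat = np.argmax(p, axis=1)
        preds[float(w)] = yhat
        f1s.append(confusion_metrics(y_true, yhat).f1)
    f1s = np.array(f1s)
    best = int(np.argmax(f1s))
    return {"weights": weights, "f1_curve": f1s, "predictions": preds,
            "best_weight": float(weights[best]), "best_f1": float(f1s[best])}


class StackedMetaLearner:
    """LDA over the 2-D (CNN, SVM) severe-probability space.

    Fit strictly on training-fold out-of-sample predictions; a singular
    within-class covariance (e.g. constant meta-features) falls back to a
    ridge-regularized (shrinkage) solver with a warning.
    """

    def __init__(self):
        self.lda = LinearDiscriminantAnalysis()
        self.fit_indices_: np.ndarray | None = None

    @staticmethod
    def _meta(p_cnn, p_svm) -> np.ndarray:
        return np.column_stack([np.asarray(p_cnn)[:, 1], np.asarray(p_svm)[:, 1]])

    def fit(self, p_cnn, p_svm, labels, indices=None):
        X = self._meta(p_cnn, p_svm)
        y = np.asarray(labels, dtype=np.int64)
        degenerate = any(np.allclose(np.var(X[y == c], axis=0), 0.0)
                         for c in np.unique(y))
        if degenerate:
            log.warning("degenerate meta-features: LDA falling back to "
                        "ridge-regularized (shrinkage) covariance")
            self.lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                self.lda.fit(X, y)
            except np.linalg.LinAlgError:
                self.lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=0.5)
                self.lda.fit(X, y)
        self.fit_indices_ = None if indices is None else np.asarray(indices)
        return self

    def predict(self, p_cnn, p_svm) -> np.ndarray:
        return self.lda.predict(self._meta(p_cnn, p_svm))

    def predict_proba(self, p_cnn, p_svm) -> np.ndarray:
        return self.lda.predict_proba(self._meta(p_cnn, p_svm))


def stack_meta_learner(p_cnn_train, p_svm_train, labels_train,
                       indices=None) -> StackedMetaLearner:
    return StackedMetaLearner().fit(p_cnn_train, p_svm_train, labels_train,
                                    indices=indices)


def downstream_svm(
    features: np.ndarray, y: np.ndarray,
    plan, repeat: int,
    kernel: str = "linear",
    n_candidates: int = 12,
    seed: int = 0,
):
    """Cross-validate a linear SVM on CNN-derived per-subject features.

    ``features`` must hold one row per subject, produced by the fold model
    under which the subject was in the TEST set (the caller guarantees no
    leakage).  Returns pooled predictions, probabilities and the per-fold
    configurations for one repeat of the shared plan.
    """
    from .svm import fit_svm, random_search_svm

    features = np.asarray(features)
    if len(features) != len(y):
        raise CoverageError("missing feature rows for some subjects")
    if not np.isfinite(features).all():
        raise CoverageError("non-finite feature rows (missing saliency?)")
    n = len(y)
    pred = np.full(n, -1, dtype=np.int64)
    proba = np.full((n, 2), np.nan)
    configs = []
    for fold, test_idx in enumerate(plan.outer[repeat]):
        train_idx = plan.outer_train(repeat, fold)
        config, _ = random_search_svm(
            features, y, train_idx, plan.inner[repeat][fold],
            kernel=kernel, n_candidates=n_candidates, seed=seed + fold)
        model = fit_svm(features[train_idx], y[train_idx], config,
                        seed=seed, fit_indices=train_idx)
        pred[test_idx] = model.predict(features[test_idx])
        proba[test_idx] = model.predict_proba(features[test_idx])
        configs.append(config)
    return {"predictions": pred, "probabilities": proba, "configs": configs}
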