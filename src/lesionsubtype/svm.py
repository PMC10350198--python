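"""Class-weighted SVM baselines on flattened morphometry maps.

Linear and radial-kernel SVMs (trained as separate models; the kernel is
never tuned) with inverse-class-frequency weighting, optional PCA or
PCA-then-ICA dimensionality reduction fit on training data only, and
random-search tuning over 300 logarithmically spaced bins per hyperparameter
on the shared cross-validation plan.

Decision values are mapped to probabilities with a logistic (Platt-style)
link, because the fusion stage consumes calibrated probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import PCA, FastICA
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .errors import ArgumentError, DegenerateLabelError, LesionSubtypeError

log = logging.getLogger(__name__)

COST_RANGE = (1e-3, 2e4)
KERNEL_SCALE_RANGE = (1e-3, 1e3)
N_BINS = 300
MAX_COMPONENTS = 75


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"              # 'linear' | 'radial'
    cost: float = 1.0
    kernel_scale: float = 1.0           # ignored for the linear kernel
    reduction: str = "none"             # 'none' | 'pca' | 'ica'
    n_components: int = 10              # ignored when reduction == 'none'

    def __post_init__(self):
        if self.kernel not in ("linear", "radial"):
            raise ArgumentError(f"unknown kernel {self.kernel!r}")
        if self.reduction not in ("none", "pca", "ica"):
            raise ArgumentError(f"unknown reduction {self.reduction!r}")
        if self.cost <= 0 or self.kernel_scale <= 0:
            raise ArgumentError("cost and kernel_scale must be positive")
        if self.reduction != "none" and not 1 <= self.n_components <= MAX_COMPONENTS:
            raise ArgumentError(f"n_components must be in [1, {MAX_COMPONENTS}]")


class Projector:
    """PCA (or PCA-then-ICA) fit on training features only.

    The ICA variant relaxes component orthogonality by running FastICA on the
    retained PCA scores; held-out data reuse the fitted loadings without any
    refit.
    """

    def __init__(self, method: str, n_components: int, seed: int = 0):
        if method not in ("pca", "ica"):
            raise ArgumentError(f"unknown projection method {method!r}")
        self.method = method
        self.n_components = n_components
        self.seed = seed
        self._pca: PCA | None = None
        self._ica: FastICA | None = None
        self.fit_indices_: np.ndarray | None = None

    def fit(self, X: np.ndarray, indices=None) -> "Projector":
        if self.n_components > min(X.shape):
            raise ArgumentError(
                f"n_components={self.n_components} exceeds min(n, p)={min(X.shape)}")
        self._pca = PCA(n_components=self.n_components, random_state=self.seed)
        scores = self._pca.fit_transform(X)
        if self.method == "ica":
            self._ica = FastICA(n_components=self.n_components,
                                random_state=self.seed, max_iter=1000)
            self._ica.fit(scores)
        self.fit_indices_ = None if indices is None else np.array(indices)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        scores = self._pca.transform(X)
        if self._ica is not None:
            scores = self._ica.transform(scores)
        return scores

    @property
    def explained_variance_ratio_(self):
        return self._pca.explained_variance_ratio_


def fit_projection(X_train: np.ndarray, method: str, n_components: int,
                   seed: int = 0, indices=None) -> Projector:
    return Projector(method, n_components, seed).fit(X_train, indices=indices)


@dataclass
class TrainedSVM:
    svc: SVC
    config: SVMConfig
    projector: Projector | None
    calibrator: LogisticRegression
    fit_indices_: np.ndarray | None = None

    def _features(self, X: np.ndarray) -> np.ndarray:
        X = X.reshape(len(X), -1)
        return self.projector.transform(X) if self.projector is not None else X

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._features(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = self.decision_values(X).reshape(-1, 1)
        return self.calibrator.predict_proba(d)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)

    def voxel_weights(self, grid_shape) -> np.ndarray:
        """Linear-SVM weights mapped back onto the input voxel grid."""
        if self.config.kernel != "linear" or self.projector is not None:
            raise LesionSubtypeError(
                "voxel weight map requires a linear kernel without reduction")
        return self.svc.coef_.ravel().reshape(grid_shape)


def fit_svm(
    X: np.ndarray, y: np.ndarray,
    config: SVMConfig,
    seed: int = 0,
    calibration_data: tuple[np.ndarray, np.ndarray] | None = None,
    fit_indices=None,
) -> TrainedSVM:
    """Fit a class-weighted SVM (hinge loss weighted by inverse frequencies).

    ``calibration_data`` (features, labels) fits the Platt link on held-out
    decision values; by default the training decisions are used.
    """
    X = np.asarray(X, dtype=np.float64).reshape(len(X), -1)
    y = np.asarray(y, dtype=np.int64)
    if not np.isfinite(X).all():
        raise ArgumentError("features must be finite")
    if np.unique(y).size < 2:
        raise DegenerateLabelError("both classes must be present")

    projector = None
    if config.reduction != "none":
        projector = fit_projection(X, config.reduction, config.n_components,
                                   seed=seed, indices=fit_indices)
        X = projector.transform(X)

    kernel = "linear" if config.kernel == "linear" else "rbf"
    gamma = "scale" if kernel == "linear" else 1.0 / (config.kernel_scale ** 2)
    svc = SVC(kernel=kernel, C=config.cost, gamma=gamma,
              class_weight="balanced", random_state=seed)
    svc.fit(X, y)

    if calibration_data is not None:
        Xc, yc = calibration_data
        Xc = np.asarray(Xc, dtype=np.float64).reshape(len(Xc), -1)
        if projector is not None:
            Xc = projector.transform(Xc)
        d = svc.decision_function(Xc).reshape(-1, 1)
        yc = np.asarray(yc, dtype=np.int64)
    else:
        d = svc.decision_function(X).reshape(-1, 1)
        yc = y
    calibrator = LogisticRegression(C=1e6)
    if np.unique(yc).size < 2:  # degenerate calibration set: fall back to train
        d = svc.decision_function(X).reshape(-1, 1)
        yc = y
    calibrator.fit(d, yc)
    return TrainedSVM(svc=svc, config=config, projector=projector,
                      calibrator=calibrator,
                      fit_indices_=None if fit_indices is None else np.array(fit_indices))


def log_spaced_bins(low: float, high: float, n_bins: int = N_BINS) -> np.ndarray:
    """Logarithmically spaced candidate values (constant consecutive ratio)."""
    if low <= 0 or high <= low:
        raise ArgumentError("range must be positive with high > low")
    return np.logspace(np.log10(low), np.log10(high), n_bins)


def hinge_loss(decision: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
    """Mean class-weighted hinge loss of decision values (labels in {0,1})."""
    sign = 2.0 * y - 1.0
    margins = np.maximum(0.0, 1.0 - sign * decision)
    return float(np.mean(weights[y] * margins))


def random_search_svm(
    X: np.ndarray, y: np.ndarray,
    outer_train: np.ndarray,
    inner_folds: list[np.ndarray],
    kernel: str = "linear",
    reduction: str = "none",
    n_candidates: int = 60,
    n_bins: int = N_BINS,
    seed: int = 0,
) -> tuple[SVMConfig, list[dict]]:
    """Random search over log-spaced hyperparameter bins.

    Candidate costs (and kernel scales for the radial kernel, and component
    counts under reduction) are drawn from ``n_bins`` log-spaced bins without
    replacement until the tuning budget is spent; the winner minimizes the
    mean class-weighted hinge loss over the inner validation folds.  The
    kernel itself is never tuned.
    """
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 31])
    costs = log_spaced_bins(*COST_RANGE, n_bins)
    scales = log_spaced_bins(*KERNEL_SCALE_RANGE, n_bins)
    n_candidates = min(n_candidates, n_bins)
    cost_pick = rng.choice(n_bins, size=n_candidates, replace=False)
    scale_pick = rng.choice(n_bins, size=n_candidates, replace=False)
    candidates = []
    for i in range(n_candidates):
        kwargs = dict(kernel=kernel, cost=float(costs[cost_pick[i]]),
                      reduction=reduction)
        if kernel == "radial":
            kwargs["kernel_scale"] = float(scales[scale_pick[i]])
        if reduction != "none":
            kwargs["n_components"] = int(rng.integers(1, MAX_COMPONENTS + 1))
        candidates.append(SVMConfig(**kwargs))
    if not candidates:
        raise ArgumentError("empty candidate set")

    from .cnn import class_weights  # inverse-frequency weights

    records = []
    X2 = X.reshape(len(X), -1)
    for config in candidates:
        losses = []
        for val_idx in inner_folds:
            val_set = set(val_idx.tolist())
            tr_idx = np.array([i for i in outer_train if i not in val_set])
            cfg = config
            if cfg.reduction != "none":
                max_nc = min(len(tr_idx), X2.shape[1], MAX_COMPONENTS)
                if cfg.n_components > max_nc:
                    cfg = replace(cfg, n_components=max_nc)
            model = fit_svm(X2[tr_idx], y[tr_idx], cfg, seed=seed)
            w = class_weights(y[tr_idx])
            losses.append(hinge_loss(model.decision_values(X2[val_idx]),
                                     y[val_idx], w))
        records.append({"config": config, "mean_inner_loss": float(np.mean(losses)),
                        "criterion": "mean_inner_loss"})
    best = min(records, key=lambda r: r["mean_inner_loss"])
    return best["config"], records
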