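"""Soft-margin linear SVM training, grid search, metrics and PCA projection.

Healthy (+1) is the positive class throughout: sensitivity is the recall of
healthy samples, specificity the recall of injured samples.  Classification
runs on the raw features (no standardization) by default.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .scenarios import Dataset

__all__ = [
    "SVMConfig",
    "ConfusionMatrix",
    "ClassificationReport",
    "DEFAULT_C_GRID",
    "train_svm",
    "grid_search",
    "evaluate",
    "metrics_from_confusion",
    "pca_project",
]

DEFAULT_C_GRID = (6e2, 6e3, 6e4, 6e5, 6e6, 6e7, 6e8)


@dataclass(frozen=True)
class SVMConfig:
    """Classifier hyperparameters.

    ``C`` follows the usual sum-of-hinge-losses convention (libsvm), so
    duplicating every training sample is equivalent to doubling ``C``; on
    separable data at large ``C`` the decision boundary is unchanged.
    """

    kernel: str = "linear"
    C: float = 6e6
    gamma: float | str = "scale"   # unused for the linear kernel
    cv_folds: int = 5
    C_grid: tuple = DEFAULT_C_GRID
    tol: float = 1e-6
    max_iter: int = 2_000_000
    standardize: bool = False

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not self.C_grid:
            raise ValueError("C grid must be non-empty")


def _fit(X: np.ndarray, y: np.ndarray, config: SVMConfig, C: float | None = None):
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if not np.isfinite(X).all():
        raise ValueError("non-finite features")
    model = SVC(
        kernel=config.kernel,
        C=C if C is not None else config.C,
        gamma=config.gamma,
        tol=config.tol,
        max_iter=config.max_iter,
    )
    if config.standardize:
        scaler = StandardScaler().fit(X)
        model.fit(scaler.transform(X), y)
        model._mw_scaler = scaler
    else:
        model.fit(X, y)
    return model


def _predict(model, X: np.ndarray) -> np.ndarray:
    scaler = getattr(model, "_mw_scaler", None)
    if scaler is not None:
        X = scaler.transform(X)
    return model.predict(X)


def train_svm(dataset: Dataset, config: SVMConfig = SVMConfig()):
    """Train on the development samples (train + validation splits)."""
    dev = dataset.part("train", "validation")
    if dataset.n_features != dev.n_features:
        raise ValueError("feature length mismatch")
    return _fit(dev.features, dev.labels, config)


def grid_search(
    dataset: Dataset, config: SVMConfig = SVMConfig()
) -> tuple[float, list[dict]]:
    """Pick C by k-fold cross-validation over the development split.

    Returns ``(best_C, table)`` where ``table`` has one row per grid value
    with the mean validation accuracy.  Ties break toward the smaller C
    (larger margin).
    """
    dev = dataset.part("train", "validation")
    if len(dev) == 0:
        raise ValueError("empty development split")
    grid = sorted(config.C_grid)
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=False)
    table = []
    for C in grid:
        accs = []
        for tr_idx, va_idx in skf.split(dev.features, dev.labels):
            m = _fit(dev.features[tr_idx], dev.labels[tr_idx], config, C=C)
            pred = _predict(m, dev.features[va_idx])
            accs.append(float(np.mean(pred == dev.labels[va_idx])))
        table.append({"C": C, "val_accuracy": float(np.mean(accs))})
    accs = np.array([row["val_accuracy"] for row in table])
    best_C = grid[int(np.argmax(accs))]   # first max = smallest C on ties
    return best_C, table


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts with healthy (+1) positive; rows actual, columns predicted."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


def metrics_from_confusion(cm: ConfusionMatrix) -> tuple[float, float | None, float | None]:
    """(accuracy, sensitivity, specificity) as fractions.

    Sensitivity is the recall of healthy (+1) samples, specificity the
    recall of injured (-1) samples; a class with no actual samples yields
    ``None`` (undefined), not 0.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acr = (cm.tp + cm.tn) / cm.total
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else None
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else None
    return acr, sens, spec


@dataclass
class ClassificationReport:
    confusion: ConfusionMatrix
    acr: float
    sens: float | None
    spec: float | None
    config: SVMConfig
    C_used: float
    train_seconds: float = float("nan")
    note: str = (
        "sensitivity/specificity follow the healthy-positive convention; "
        "some published tables swap the two columns"
    )

    def to_dict(self) -> dict:
        return {
            "confusion": asdict(self.confusion),
            "acr": self.acr,
            "sens": self.sens,
            "spec": self.spec,
            "C": self.C_used,
            "kernel": self.config.kernel,
            "train_seconds": self.train_seconds,
            "note": self.note,
        }

    def text_table(self) -> str:
        def pct(x):
            return "undef" if x is None else f"{100 * x:.2f}%"
        cm = self.confusion
        return (
            f"C = {self.C_used:g} ({self.config.kernel})\n"
            f"            pred healthy  pred injured\n"
            f"act healthy {cm.tp:12d}  {cm.fn:12d}\n"
            f"act injured {cm.fp:12d}  {cm.tn:12d}\n"
            f"acr = {pct(self.acr)}  sens = {pct(self.sens)}  spec = {pct(self.spec)}\n"
        )


def evaluate(model, dataset: Dataset, split: str = "test") -> ClassificationReport:
    """Confusion matrix and metrics of ``model`` on a dataset split."""
    test = dataset.part(split)
    if len(test) == 0:
        raise ValueError(f"empty {split} split")
    n_expect = getattr(model, "n_features_in_", test.n_features)
    if test.n_features != n_expect:
        raise ValueError(
            f"feature length mismatch: model expects {n_expect}, "
            f"data has {test.n_features}"
        )
    pred = _predict(model, test.features)
    y = test.labels
    cm = ConfusionMatrix(
        tp=int(np.sum((y == 1) & (pred == 1))),
        fn=int(np.sum((y == 1) & (pred == -1))),
        fp=int(np.sum((y == -1) & (pred == 1))),
        tn=int(np.sum((y == -1) & (pred == -1))),
    )
    acr, sens, spec = metrics_from_confusion(cm)
    return ClassificationReport(
        confusion=cm, acr=acr, sens=sens, spec=spec,
        config=SVMConfig(C=float(model.C), kernel=model.kernel),
        C_used=float(model.C),
    )


def run_classification(
    dataset: Dataset, config: SVMConfig = SVMConfig(), *, do_grid_search: bool = True
) -> ClassificationReport:
    """Grid-search C (optional), train on the development split, evaluate on test."""
    if do_grid_search:
        best_C, _ = grid_search(dataset, config)
    else:
        best_C = config.C
    t0 = time.perf_counter()
    model = _fit(dataset.part("train", "validation").features,
                 dataset.part("train", "validation").labels, config, C=best_C)
    dt = time.perf_counter() - t0
    report = evaluate(model, dataset)
    report.train_seconds = dt
    return report


def pca_project(features: np.ndarray, n_components: int = 3) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered principal-axis projection for visualization.

    Returns ``(coords, explained_variance_ratio)``.  Component signs follow a
    deterministic convention: the largest-magnitude loading is positive.
    Train and test blocks are projected separately by calling this twice.
    """
    X = np.asarray(features, dtype=float)
    if n_components > X.shape[1]:
        raise ValueError("n_components exceeds feature dimension")
    if n_components > len(X):
        raise ValueError("n_components exceeds sample count")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt[:n_components]
    for i in range(n_components):
        j = int(np.argmax(np.abs(V[i])))
        if V[i, j] < 0:
            V[i] = -V[i]
    coords = Xc @ V.T
    var = s**2
    evr = var[:n_components] / var.sum() if var.sum() > 0 else np.zeros(n_components)
    return coords, evr
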