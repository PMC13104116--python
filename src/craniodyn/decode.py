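"""Population decoding of grating orientation.

Decoding accuracy is the fraction of correctly classified trials,
Acc = N_correct / N_total, from a linear-kernel max-margin (SVM)
classifier under stratified k-fold cross-validation with per-fold feature
standardization.  A companion LDA embedding projects trial responses onto
the (≤ 3-dimensional) subspace separating the four orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .data import CalciumDataset
from .respond import DetectionParams, trial_windows

__all__ = [
    "TrialFeatures",
    "DecodingResult",
    "trial_features",
    "decoding_accuracy",
    "lda_embedding",
    "LDAEmbedding",
]


@dataclass(frozen=True)
class TrialFeatures:
    """(n_trials × n_neurons) per-trial mean ΔF/F in the stimulus window."""

    X: np.ndarray
    labels: np.ndarray  # orientation (deg) per trial
    neuron_ids: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        labels = np.asarray(self.labels, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "neuron_ids", np.asarray(self.neuron_ids, dtype=int))
        if X.ndim != 2 or len(labels) != X.shape[0]:
            raise ValueError("X must be (n_trials, n_neurons) aligned with labels")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass(frozen=True)
class DecodingResult:
    """Cross-validated decoding outcome with Acc = n_correct / n_total."""

    accuracy: float
    fold_accuracies: np.ndarray
    confusion: pd.DataFrame  # rows = true class, columns = predicted
    n_correct: int
    n_total: int

    def __post_init__(self) -> None:
        assert self.n_total > 0
        assert np.isclose(self.accuracy, self.n_correct / self.n_total)


def trial_features(
    dataset: CalciumDataset,
    neurons: np.ndarray | None = None,
    stim_window: float | None = None,
) -> TrialFeatures:
    """Build the trial × neuron feature matrix of stimulus-window means."""
    if neurons is None:
        neurons = np.arange(dataset.n_neurons)
    else:
        neurons = np.asarray(neurons)
        if neurons.dtype == bool:
            neurons = np.flatnonzero(neurons)
        if len(neurons) == 0:
            raise ValueError("empty neuron subset")
    params = DetectionParams(stim_window=stim_window or dataset.schedule.duration)
    windows = trial_windows(dataset.schedule, dataset.frame_rate, params)
    sub = dataset.traces[neurons]
    X = np.column_stack(
        [sub[:, w[0]].mean(axis=1) for w in windows]).T
    return TrialFeatures(X=X, labels=dataset.schedule.orientations,
                         neuron_ids=neurons)


def decoding_accuracy(
    features: TrialFeatures,
    folds: int = 4,
    seed: int | None = 0,
    C: float = 1.0,
) -> DecodingResult:
    """Stratified k-fold cross-validated orientation decoding.

    Linear-kernel SVM, one-vs-rest, features z-scored per fold on training
    data only; accuracy pooled over all held-out trials.  Deterministic
    given ``seed`` (fold shuffling).
    """
    classes = features.classes
    counts = pd.Series(features.labels).value_counts()
    if counts.min() < folds:
        raise ValueError(
            f"stratification violated: a class has {counts.min()} trials "
            f"but {folds} folds were requested")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    y_true = np.empty(features.n_trials)
    y_pred = np.empty(features.n_trials)
    fold_acc = []
    for train, test in skf.split(features.X, features.labels):
        clf = make_pipeline(
            StandardScaler(),
            OneVsRestClassifier(SVC(kernel="linear", C=C)),
        )
        clf.fit(features.X[train], features.labels[train])
        pred = clf.predict(features.X[test])
        y_true[test] = features.labels[test]
        y_pred[test] = pred
        fold_acc.append(float(np.mean(pred == features.labels[test])))
    n_correct = int(np.count_nonzero(y_true == y_pred))
    n_total = features.n_trials
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    confusion = pd.DataFrame(conf, index=classes, columns=classes)
    return DecodingResult(
        accuracy=n_correct / n_total,
        fold_accuracies=np.asarray(fold_acc),
        confusion=confusion,
        n_correct=n_correct,
        n_total=n_total,
    )


@dataclass(frozen=True)
class LDAEmbedding:
    """Low-dimensional trial coordinates from linear discriminant analysis."""

    coords: np.ndarray  # (n_trials, n_dims)
    labels: np.ndarray
    centroids: pd.DataFrame  # class → centroid coordinates
    shrinkage_used: bool


def lda_embedding(features: TrialFeatures, n_dims: int = 3) -> LDAEmbedding:
    """Project trials onto the discriminant subspace of the orientations.

    ``n_dims`` is bounded by classes − 1 (= 3 for four orientations).  A
    singular within-class scatter (e.g. collinear features) triggers an
    automatic fall-back to the shrinkage-regularized eigen solver, noted
    in the returned metadata; fully degenerate inputs (zero variance
    everywhere) embed at the origin.
    """
    classes = features.classes
    max_dims = len(classes) - 1
    if n_dims > max_dims:
        raise ValueError(f"n_dims must be <= n_classes - 1 = {max_dims}")
    if n_dims < 1:
        raise ValueError("n_dims must be positive")

    if np.allclose(features.X.var(axis=0), 0.0):
        coords = np.zeros((features.n_trials, n_dims))
        centroids = pd.DataFrame(
            np.zeros((len(classes), n_dims)), index=classes)
        return LDAEmbedding(coords=coords, labels=features.labels,
                            centroids=centroids, shrinkage_used=False)

    shrinkage_used = False
    lda = LinearDiscriminantAnalysis(solver="svd", n_components=n_dims)
    try:
        coords = lda.fit_transform(features.X, features.labels)
        if not np.all(np.isfinite(coords)):
            raise np.linalg.LinAlgError("non-finite LDA projection")
    except (np.linalg.LinAlgError, ValueError):
        shrinkage_used = True
        lda = LinearDiscriminantAnalysis(
            solver="eigen", shrinkage="auto", n_components=n_dims)
        coords = lda.fit_transform(features.X, features.labels)
    cent = np.vstack(
        [coords[features.labels == c].mean(axis=0) for c in classes])
    centroids = pd.DataFrame(cent, index=classes)
    return LDAEmbedding(coords=coords, labels=features.labels,
                        centroids=centroids, shrinkage_used=shrinkage_used)
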