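"""PLS regression, metrics, repeated cross-validation and classifiers.

Partial least squares (NIPALS, via scikit-learn) predicts the four quality
parameters from preprocessed absorbance spectra; the classifier harness runs
the five families compared for direct maturity grading (linear discriminant,
support vector, k-nearest-neighbour, multilayer perceptron, decision tree)
under repeated stratified k-fold cross-validation with any spectral pipeline
refitted inside each training fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, RepeatedStratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from mangonir.data import MATURITY_CLASSES

CLASSIFIER_FAMILIES = (
    "linear-discriminant",
    "support-vector",
    "k-nearest-neighbor",
    "multilayer-perceptron",
    "decision-tree",
)


@dataclass(frozen=True)
class CVConfig:
    """Repeated stratified k-fold settings: 10 folds, 3 repeats by default."""

    folds: int = 10
    repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError(f"folds must be >= 2, got {self.folds}")
        if self.repeats < 1:
            raise ValueError(f"repeats must be >= 1, got {self.repeats}")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus optional hyperparameter overrides."""

    family: str
    hyperparameters: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"family must be one of {CLASSIFIER_FAMILIES}, got {self.family!r}"
            )
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(
                self, "hyperparameters", tuple(sorted(self.hyperparameters.items()))
            )

    def build(self, seed: int = 0):
        params = dict(self.hyperparameters)
        if self.family == "linear-discriminant":
            return LinearDiscriminantAnalysis(**params)
        if self.family == "support-vector":
            return SVC(**params)
        if self.family == "k-nearest-neighbor":
            return KNeighborsClassifier(**params)
        if self.family == "multilayer-perceptron":
            params.setdefault("max_iter", 500)
            return MLPClassifier(random_state=seed, **params)
        return DecisionTreeClassifier(random_state=seed, **params)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def r2(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.size < 2:
        raise ValueError("R2 needs at least two observations")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot <= 0:
        raise ValueError("R2 undefined for constant y")
    return float(1.0 - np.sum((y - y_pred) ** 2) / ss_tot)


def rmse(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Root mean squared error, in the target's units."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.size == 0:
        raise ValueError("RMSE undefined for empty input")
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have the same length")
    return float(np.sqrt(np.mean((y - y_pred) ** 2)))


# ---------------------------------------------------------------------------
# PLS regression
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted PLS1 model; ``n_components=0`` degenerates to the mean of y."""

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    _pls: PLSRegression | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValueError(
                f"expected {self.x_mean.size} features, got {X.shape[1]}"
            )
        if self._pls is None:
            return np.full(X.shape[0], self.y_mean)
        return self._pls.predict(X).ravel()


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS with internal centering of X and y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y lengths differ")
    if np.var(y) <= 0:
        raise ValueError("y has zero variance")
    k_max = min(n - 1, p)
    if not 0 <= n_components <= k_max:
        raise ValueError(f"n_components must be in [0, {k_max}], got {n_components}")
    model = PLSModel(
        n_components=n_components, x_mean=X.mean(axis=0), y_mean=float(y.mean())
    )
    if n_components == 0:
        return model
    pls = PLSRegression(n_components=n_components, scale=False, tol=1e-10, max_iter=500)
    with warnings.catch_warnings():
        # with k close to rank(X) the final y residual can be ~0; harmless
        warnings.simplefilter("ignore", UserWarning)
        pls.fit(X, y)
    model._pls = pls
    return model


def predict_pls(model: PLSModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    k_max: int,
    cv: CVConfig | None = None,
) -> tuple[int, np.ndarray]:
    """Choose the component count minimising cross-validated RMSE.

    Returns ``(best_k, curve)`` where ``curve[k-1]`` is the CV RMSE at k
    components; ties go to the smallest k.
    """
    cv = cv or CVConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    # smallest training fold has about n*(folds-1)/folds samples
    hard_max = min(X.shape[1], X.shape[0] * (cv.folds - 1) // cv.folds - 1)
    if not 1 <= k_max <= max(hard_max, 1):
        raise ValueError(f"k_max must be in [1, {hard_max}], got {k_max}")
    sq_errors = np.zeros(k_max)
    counts = 0
    for rep in range(cv.repeats):
        folds = KFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed + rep)
        for train_idx, test_idx in folds.split(X):
            counts += test_idx.size
            for k in range(1, k_max + 1):
                m = fit_pls(X[train_idx], y[train_idx], k)
                resid = y[test_idx] - m.predict(X[test_idx])
                sq_errors[k - 1] += np.sum(resid**2)
    curve = np.sqrt(sq_errors / counts)
    best_k = int(np.argmin(curve)) + 1  # argmin takes the first (smallest) k on ties
    return best_k, curve


# ---------------------------------------------------------------------------
# classification harness
# ---------------------------------------------------------------------------

def cross_validate_classifier(
    X: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    cv: CVConfig | None = None,
    preprocessor=None,
) -> float:
    """Mean accuracy (%) over repeated stratified k-fold.

    ``preprocessor(train_X, test_X) -> (train_T, test_T)`` is refitted inside
    every training fold so held-out scans never inform fitted state (MSC/EMSC
    references, resampling grids).
    """
    cv = cv or CVConfig()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < cv.folds:
        raise ValueError(
            f"every class needs >= {cv.folds} members for {cv.folds}-fold CV"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=cv.folds, n_repeats=cv.repeats, random_state=cv.seed
    )
    accuracies = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train_idx, test_idx in splitter.split(X, labels):
            train_X, test_X = X[train_idx], X[test_idx]
            if preprocessor is not None:
                train_X, test_X = preprocessor(train_X, test_X)
            clf = spec.build(seed=cv.seed)
            clf.fit(train_X, labels[train_idx])
            accuracies.append(np.mean(clf.predict(test_X) == labels[test_idx]))
    return float(np.mean(accuracies) * 100.0)


def confusion_matrix(
    true_labels: np.ndarray, predicted_labels: np.ndarray
) -> np.ndarray:
    """5x5 count table; rows = actual class, columns = predicted class."""
    true_labels = np.asarray(true_labels, dtype=int)
    predicted_labels = np.asarray(predicted_labels, dtype=int)
    if true_labels.shape != predicted_labels.shape:
        raise ValueError("label vectors must have equal length")
    index = {cls: i for i, cls in enumerate(MATURITY_CLASSES)}
    table = np.zeros((5, 5), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown maturity label in ({t}, {p})")
        table[index[t], index[p]] += 1
    return table


def accuracy_from_confusion(table: np.ndarray) -> float:
    """Overall accuracy (%) = trace / total."""
    table = np.asarray(table)
    total = table.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(table) / total * 100.0)
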