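"""One-vs-rest classifier bank for the five stepping motions.

Instead of a single five-class model, one binary classifier per motion
(jump, left, right, forward, backward) decides "my motion" vs "anything
else".  This keeps each problem simple, allows per-motion feature
tailoring later, and mirrors how the system is evaluated (per-motion
confusion counts).  Three interchangeable backends are supported:

* ``decision_tree`` — impurity-split binary tree (Gini, depth-capped),
* ``knn`` — majority vote of the k nearest neighbours (Euclidean),
* ``svm`` — max-margin hyperplane with an RBF kernel.

Features are standardised (train-set mean/std) for the distance-based
backends.  Each binary problem is roughly 1:3 imbalanced, so
inverse-frequency class weights are on by default where the backend
supports them.

Arbitration of the five binary outputs into one event is plumbing this
package defines: if exactly one classifier fires, that motion wins; if
none fires the event is ``none``; if several fire, the largest decision
score wins, ties broken by the fixed motion order above.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_SCHEMA_VERSION, FEATURE_NAMES

__all__ = [
    "MotionLabel",
    "MOTIONS",
    "Backend",
    "MotionClassifier",
    "ClassifierBank",
    "SchemaMismatch",
    "DegenerateTraining",
    "train_bank",
    "predict_event",
]


class MotionLabel(str, enum.Enum):
    JUMP = "jump"
    LEFT = "left"
    RIGHT = "right"
    FORWARD = "forward"
    BACKWARD = "backward"
    NONE = "none"


#: fixed arbitration/tie-break order
MOTIONS: tuple[MotionLabel, ...] = (
    MotionLabel.JUMP, MotionLabel.LEFT, MotionLabel.RIGHT,
    MotionLabel.FORWARD, MotionLabel.BACKWARD,
)


class Backend(str, enum.Enum):
    DECISION_TREE = "decision_tree"
    KNN = "knn"
    SVM = "svm"


class SchemaMismatch(ValueError):
    """Feature vector does not match the schema the bank was trained on."""


class DegenerateTraining(ValueError):
    """A binary problem with fewer than two classes cannot be trained."""


DEFAULT_HYPERPARAMS = {
    Backend.DECISION_TREE: {"criterion": "gini", "max_depth": 10},
    Backend.KNN: {"n_neighbors": 5, "weights": "uniform"},
    Backend.SVM: {"kernel": "rbf", "C": 1.0, "gamma": "scale"},
}


def _make_estimator(backend: Backend, hyperparams: dict, seed: int):
    hp = {**DEFAULT_HYPERPARAMS[backend], **(hyperparams or {})}
    if backend is Backend.DECISION_TREE:
        return DecisionTreeClassifier(class_weight="balanced", random_state=seed, **hp)
    if backend is Backend.KNN:
        if hp["n_neighbors"] < 1:
            raise ValueError("n_neighbors must be >= 1")
        return Pipeline([("scale", StandardScaler()),
                         ("knn", KNeighborsClassifier(**hp))])
    return Pipeline([("scale", StandardScaler()),
                     ("svm", SVC(class_weight="balanced", random_state=seed, **hp))])


@dataclass
class MotionClassifier:
    """Binary classifier for one motion vs the rest."""

    motion: MotionLabel
    backend: Backend
    estimator: object
    feature_schema_version: str = FEATURE_SCHEMA_VERSION

    def predict(self, X: np.ndarray) -> np.ndarray:
        """1 = this motion, 0 = not."""
        return np.asarray(self.estimator.predict(np.atleast_2d(X)), int)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Signed decision score (positive favours this motion)."""
        X = np.atleast_2d(X)
        est = self.estimator
        if hasattr(est, "decision_function"):
            try:
                return np.asarray(est.decision_function(X), float)
            except AttributeError:  # pipeline without decision_function
                pass
        proba = est.predict_proba(X)
        pos = list(est.classes_).index(1)
        return np.asarray(proba[:, pos], float) - 0.5


class ClassifierBank:
    """Five one-vs-rest classifiers sharing a backend and feature schema."""

    def __init__(self, classifiers: dict[MotionLabel, MotionClassifier],
                 backend: Backend, seed: int,
                 feature_schema_version: str = FEATURE_SCHEMA_VERSION):
        if set(classifiers) != set(MOTIONS):
            raise ValueError("bank needs exactly one classifier per motion")
        self.classifiers = classifiers
        self.backend = backend
        self.seed = seed
        self.feature_schema_version = feature_schema_version

    # -- prediction --------------------------------------------------------

    def _check(self, fv: np.ndarray) -> np.ndarray:
        fv = np.asarray(fv, float)
        if fv.shape[-1] != len(FEATURE_NAMES):
            raise SchemaMismatch(
                f"expected {len(FEATURE_NAMES)} features, got {fv.shape[-1]}")
        if self.feature_schema_version != FEATURE_SCHEMA_VERSION:
            raise SchemaMismatch(
                f"bank trained on schema {self.feature_schema_version}, "
                f"runtime schema is {FEATURE_SCHEMA_VERSION}")
        return fv

    def predict_event(self, fv: np.ndarray) -> tuple[MotionLabel, float]:
        """Arbitrate the five binary outputs into one motion event."""
        fv = self._check(fv).reshape(1, -1)
        fired: list[tuple[MotionLabel, float]] = []
        scores: dict[MotionLabel, float] = {}
        for m in MOTIONS:
            clf = self.classifiers[m]
            scores[m] = float(clf.score(fv)[0])
            if int(clf.predict(fv)[0]) == 1:
                fired.append((m, scores[m]))
        if not fired:
            return MotionLabel.NONE, max(scores.values())
        if len(fired) == 1:
            return fired[0]
        # several fired: highest score wins; MOTIONS order breaks ties
        best = max(fired, key=lambda ms: ms[1])
        return best

    def predict_labels(self, X: np.ndarray) -> list[MotionLabel]:
        X = self._check(X)
        return [self.predict_event(row)[0] for row in np.atleast_2d(X)]

    def binary_predictions(self, X: np.ndarray) -> dict[MotionLabel, np.ndarray]:
        """Raw per-motion binary outputs (for confusion accounting)."""
        X = self._check(np.atleast_2d(X))
        return {m: self.classifiers[m].predict(X) for m in MOTIONS}

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Versioned on-disk bundle: meta.json + joblib payload."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "backend": self.backend.value,
            "seed": self.seed,
            "feature_schema_version": self.feature_schema_version,
            "feature_names": list(FEATURE_NAMES),
            "motions": [m.value for m in MOTIONS],
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
        joblib.dump({m.value: self.classifiers[m].estimator for m in MOTIONS},
                    path / "bank.joblib")

    @classmethod
    def load(cls, path) -> "ClassifierBank":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        estimators = joblib.load(path / "bank.joblib")
        backend = Backend(meta["backend"])
        classifiers = {
            MotionLabel(m): MotionClassifier(
                motion=MotionLabel(m), backend=backend, estimator=est,
                feature_schema_version=meta["feature_schema_version"])
            for m, est in estimators.items()
        }
        return cls(classifiers, backend=backend, seed=meta["seed"],
                   feature_schema_version=meta["feature_schema_version"])


def train_bank(X: np.ndarray, labels, backend: Backend | str = Backend.SVM,
               hyperparams: dict | None = None, seed: int = 0) -> ClassifierBank:
    """Fit one m-vs-rest classifier per motion on the full set.

    ``labels`` are MotionLabel values (or their strings); every binary
    problem must contain both classes.
    """
    backend = Backend(backend)
    X = np.asarray(X, float)
    y = np.array([MotionLabel(l).value for l in labels])
    if X.shape[0] != y.size:
        raise ValueError("X and labels disagree in length")
    if X.shape[1] != len(FEATURE_NAMES):
        raise SchemaMismatch(
            f"expected {len(FEATURE_NAMES)} features, got {X.shape[1]}")
    classifiers = {}
    for m in MOTIONS:
        y_bin = (y == m.value).astype(int)
        if len(np.unique(y_bin)) < 2:
            raise DegenerateTraining(f"motion {m.value}: single-class training set")
        est = _make_estimator(backend, hyperparams, seed)
        est.fit(X, y_bin)
        classifiers[m] = MotionClassifier(motion=m, backend=backend, estimator=est)
    return ClassifierBank(classifiers, backend=backend, seed=seed)


def predict_event(bank: ClassifierBank, fv: np.ndarray) -> tuple[MotionLabel, float]:
    """Functional alias for :meth:`ClassifierBank.predict_event`."""
    return bank.predict_event(fv)
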