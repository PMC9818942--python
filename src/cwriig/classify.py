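"""Data splitting, augmentation, classical classifiers and metrics.

Malignant is the positive class throughout: sensitivity is recall on
malignant, specificity recall on benign, PPV/NPV the corresponding
precisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

__all__ = ["Metrics", "grouped_split", "augment_translate", "fit_classical",
           "crossval_accuracy", "evaluate_predictions"]


@dataclass
class Metrics:
    """Confusion counts and the derived rates; undefined rates are NaN."""

    tp: int
    tn: int
    fp: int
    fn: int

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den else math.nan

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def f1(self) -> float:
        p, s = self.ppv, self.sensitivity
        if math.isnan(p) or math.isnan(s) or (p + s) == 0:
            return math.nan
        return 2 * p * s / (p + s)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "ppv": self.ppv, "npv": self.npv,
            "f1": self.f1,
        }


def evaluate_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Confusion-matrix metrics with label 1 (malignant) positive."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must align")
    return Metrics(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def grouped_split(samples, test_fraction: float, seed: int) -> tuple[list, list]:
    """Split by source image so no source contributes to both sides.

    Every sample must carry a ``source_id``; all augmented variants of a
    source follow it into the same side.  About ``test_fraction`` of the
    distinct sources (at least one) form the test side.
    """
    samples = list(samples)
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    ids = []
    for s in samples:
        sid = getattr(s, "source_id", None)
        if sid is None:
            raise ValueError("every sample needs a source_id for a grouped split")
        ids.append(sid)
    unique = sorted(set(ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(unique)
    n_test = max(1, round(test_fraction * len(unique)))
    test_ids = set(unique[:n_test])
    train = [s for s, sid in zip(samples, ids) if sid not in test_ids]
    test = [s for s, sid in zip(samples, ids) if sid in test_ids]
    return train, test


def augment_translate(image: np.ndarray, n_variants: int, max_shift: int = 11,
                      seed: int = 0) -> list[np.ndarray]:
    """Integer translations of 1..max_shift px in both axes, edge-replicated.

    No rotation or scaling (those would destroy size- and
    orientation-dependent features); shifts are never (0, 0).
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_variants):
        dy = int(rng.integers(1, max_shift + 1)) * (1 if rng.random() < 0.5 else -1)
        dx = int(rng.integers(1, max_shift + 1)) * (1 if rng.random() < 0.5 else -1)
        pad_y = (dy, 0) if dy >= 0 else (0, -dy)
        pad_x = (dx, 0) if dx >= 0 else (0, -dx)
        p = np.pad(img, (pad_y, pad_x), mode="edge")
        h, w = img.shape
        y0 = 0 if dy >= 0 else -dy
        x0 = 0 if dx >= 0 else -dx
        out.append(p[y0:y0 + h, x0:x0 + w])
    return out


def crossval_accuracy(features: np.ndarray, labels: np.ndarray, kind: str,
                      k: int = 10, seed: int = 0) -> float:
    """Mean k-fold cross-validated accuracy of a classical classifier.

    Optional evaluation mode (hyper-parameter searches); the default
    experiment protocol is the grouped single split.
    """
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    clf = _make_classifier(kind, seed)
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(clf, features, labels, cv=cv)))


def _make_classifier(kind: str, seed: int):
    if kind == "svm":
        return SVC(random_state=seed)
    if kind == "knn":
        return KNeighborsClassifier()
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown classifier kind {kind!r}")


def fit_classical(features: np.ndarray, labels: np.ndarray, kind: str, seed: int = 0):
    """Train an SVM / KNN / random forest on pooled CNN features.

    Library default settings are used for each classifier; only the RNG is
    pinned where the classifier has one.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must align")
    clf = _make_classifier(kind, seed)
    clf.fit(features, labels)
    return clf
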