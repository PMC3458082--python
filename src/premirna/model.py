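"""Bagged three-learner ensemble, F-score feature ranking and evaluation.

The committee holds K bootstrap resamples x 3 complementary base learners:
a Gaussian-kernel maximum-margin classifier (SVM), Gaussian Naive Bayes,
and a best-first binary decision tree (Gini impurity — nodes whose split
most reduces impurity are expanded first, which for a fully grown tree
yields the same tree as depth-first growth).  A candidate's label is the
majority over all 3K votes; the positive-vote fraction doubles as a
confidence score in [0, 1], where 1.0 means every committee member agreed.
Vote ties go to the negative class: in genome-wide scans false positives
are the expensive error.

Feature ranking uses a Fisher-type F-score per feature: the squared
deviations of the class means from the overall mean, divided by the sum
of the unbiased within-class scatters.
"""

from __future__ import annotations

import dataclasses
import hashlib
import pickle
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


class ModelError(ValueError):
    pass


def f_score(pos: Sequence[float], neg: Sequence[float]) -> float:
    """Fisher-type discrimination score of one feature.

    ((m+ - m)^2 + (m- - m)^2) / (s+ + s-) with s the unbiased within-class
    scatter sum((x - m_c)^2) / (n_c - 1).  Zero when the two classes are
    identical in mean and scatter; infinite for perfectly separated
    zero-variance classes.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size < 2 or neg.size < 2:
        raise ModelError("need >= 2 samples per class")
    m_all = np.concatenate([pos, neg]).mean()
    numer = (pos.mean() - m_all) ** 2 + (neg.mean() - m_all) ** 2
    denom = pos.var(ddof=1) + neg.var(ddof=1)
    if denom == 0.0:
        return 0.0 if numer == 0.0 else float("inf")
    return float(numer / denom)


def rank_features(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """F-score of every column of X; y holds binary labels (1 positive)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    pos, neg = X[y == 1], X[y == 0]
    return np.array([f_score(pos[:, j], neg[:, j]) for j in range(X.shape[1])])


@dataclasses.dataclass
class BaggingConfig:
    """Committee shape and seeding.  ``n_bags`` is K, the number of
    bootstrap resamples; ``sample_size`` N defaults to the training-set
    size.  The SVM kernel width follows the 1/n_features heuristic."""

    n_bags: int = 10
    sample_size: int | None = None
    seed: int = 0
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.n_bags < 1:
            raise ModelError("n_bags must be >= 1")
        if self.sample_size is not None and self.sample_size < 1:
            raise ModelError("sample_size must be >= 1")


def _base_learners(cfg: BaggingConfig, rs: int):
    return [
        ("svm", SVC(kernel="rbf", C=cfg.svm_c, gamma="auto", random_state=rs), True),
        ("nb", GaussianNB(), False),
        ("bftree", DecisionTreeClassifier(criterion="gini", random_state=rs), False),
    ]


@dataclasses.dataclass
class BaggedModel:
    """K x 3 trained base classifiers with their scalers and vote rule."""

    members: list  # (name, scaler | None, fitted classifier)
    n_features: int
    config: BaggingConfig
    layout_hash: str = ""

    def votes(self, X: np.ndarray) -> np.ndarray:
        """(n_samples, 3K) matrix of component votes in {0, 1}."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ModelError(
                f"expected {self.n_features} features, got {X.shape[1]}"
            )
        cols = []
        for _, scaler, clf in self.members:
            Xs = scaler.transform(X) if scaler is not None else X
            cols.append(clf.predict(Xs))
        return np.stack(cols, axis=1)

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Majority labels and positive-vote fractions; ties -> negative."""
        v = self.votes(X)
        frac = v.mean(axis=1)
        labels = (frac > 0.5).astype(int)
        return labels, frac

    def save(self, path: str | Path) -> None:
        Path(path).write_bytes(pickle.dumps(self))

    @classmethod
    def load(cls, path: str | Path) -> "BaggedModel":
        model = pickle.loads(Path(path).read_bytes())
        if not isinstance(model, cls):
            raise ModelError("file does not contain a bagged model")
        return model


def layout_hash(feature_names: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(feature_names).encode()).hexdigest()[:16]


def bag_train(
    X: np.ndarray,
    y: np.ndarray,
    cfg: BaggingConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> BaggedModel:
    """Train the committee: K seeded bootstrap resamples (with replacement,
    size N), each fitted by all three base learners.  Standardization is
    fit per-resample on the bootstrap sample only and applied to the SVM;
    the tree and Naive Bayes consume raw values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.isnan(X).any():
        raise ModelError("feature matrix contains NaN")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ModelError("training data must contain both classes")
    cfg = cfg or BaggingConfig()
    n = X.shape[0]
    size = cfg.sample_size or n
    rng = np.random.default_rng(cfg.seed)
    members = []
    for k in range(cfg.n_bags):
        # resample until both classes appear (guaranteed to terminate)
        while True:
            idx = rng.integers(0, n, size=size)
            if len(np.unique(y[idx])) == 2:
                break
        Xb, yb = X[idx], y[idx]
        rs = int(rng.integers(0, 2**31 - 1))
        for name, clf, needs_scaling in _base_learners(cfg, rs):
            if needs_scaling:
                scaler = StandardScaler().fit(Xb)
                clf.fit(scaler.transform(Xb), yb)
                members.append((name, scaler, clf))
            else:
                clf.fit(Xb, yb)
                members.append((name, None, clf))
    h = layout_hash(feature_names) if feature_names is not None else ""
    return BaggedModel(members=members, n_features=X.shape[1], config=cfg,
                       layout_hash=h)


def bag_predict(model: BaggedModel, x: np.ndarray) -> tuple[int, float]:
    """Label and vote fraction for a single feature vector."""
    labels, frac = model.predict(np.atleast_2d(x))
    return int(labels[0]), float(frac[0])


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ModelError("confusion counts must be non-negative")


def metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity and accuracy as percentages, plus the
    Matthews correlation coefficient::

        Sn  = TP / (TP + FN)
        Sp  = TN / (TN + FP)
        Acc = (TN + TP) / (TN + FP + TP + FN)
        MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))
    """
    tp, fn, tn, fp = c.tp, c.fn, c.tn, c.fp
    denoms = [tp + fn, tn + fp, tp + fp, tn + fn]
    if any(d == 0 for d in denoms):
        raise ModelError("metric denominator is zero")
    sn = 100.0 * tp / (tp + fn)
    sp = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / (tp + fn + tn + fp)
    mcc = (tp * tn - fp * fn) / np.sqrt(
        float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    )
    return {"Sn": sn, "Sp": sp, "Acc": acc, "MCC": float(mcc)}


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
    )


def cross_validate_roc(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    cfg: BaggingConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Stratified k-fold cross-validation pooling per-fold vote fractions
    into one ROC curve; returns (fpr, tpr, auc)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    cfg = cfg or BaggingConfig()
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ModelError(f"need >= {folds} samples per class for {folds}-fold CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    scores = np.zeros(len(y))
    for fold_i, (train, test) in enumerate(skf.split(X, y)):
        fold_cfg = dataclasses.replace(cfg, seed=cfg.seed + fold_i + 1)
        model = bag_train(X[train], y[train], fold_cfg)
        _, frac = model.predict(X[test])
        scores[test] = frac
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    return fpr, tpr, float(_sk_auc(fpr, tpr))
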