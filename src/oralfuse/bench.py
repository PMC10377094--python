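"""Multi-classifier benchmark over feature tables.

Five classifiers are benchmarked: a softmax (multinomial logistic) linear
model, a decision tree, a 100-tree random forest, k-nearest-neighbours
(k = 5) and a linear-kernel SVM.  Evaluation uses a stratified 80/10/10
train/validation/test split repeated over three folds with rotated,
disjoint test partitions; the best fold (maximal test accuracy) is flagged
as in the single-best-fold reporting convention, and mean +/- sd across
folds is emitted alongside.

Features are standardized with train-fold statistics before the distance-
and margin-based classifiers (knn, svm, softmax); the tree models see raw
features.  Reported metrics are always recomputed from the stored
confusion matrix, so report and matrix cannot drift apart.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .metrics import POSITIVE_LABEL, ConfusionMatrix, MetricReport, confusion, metrics
from .table import FeatureTable

__all__ = [
    "CLASSIFIER_NAMES",
    "SplitSpec",
    "ClassifierSpec",
    "FoldResult",
    "CVResult",
    "make_splits",
    "fit_predict",
    "run_bench",
    "default_specs",
]

CLASSIFIER_NAMES = ("softmax", "dt", "rf", "knn", "svm")

_SCALED = {"softmax", "knn", "svm"}


@dataclass(frozen=True)
class SplitSpec:
    """Stratified 80/10/10 split, three rotated folds."""

    train_fraction: float = 0.8
    validation_fraction: float = 0.1
    test_fraction: float = 0.1
    folds: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        total = self.train_fraction + self.validation_fraction + self.test_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")
        if self.folds < 1:
            raise ValueError("folds must be >= 1")


@dataclass(frozen=True)
class ClassifierSpec:
    """One benchmark entry; ``params`` override the documented defaults."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )


@dataclass
class FoldResult:
    fold: int
    cm: ConfusionMatrix
    report: MetricReport
    scores: np.ndarray  # positive-class test scores, usable for ROC
    test_labels: np.ndarray


@dataclass
class CVResult:
    classifier: str
    per_fold: list[FoldResult]
    best_fold: int  # index of the accuracy-maximizing fold

    @property
    def best(self) -> FoldResult:
        return self.per_fold[self.best_fold]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([f.report.ac for f in self.per_fold]))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std([f.report.ac for f in self.per_fold]))


def make_splits(
    labels: np.ndarray, spec: SplitSpec
) -> list[tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per fold: disjoint (train, validation, test) index arrays,
    stratified by class, reproducible from ``spec.seed``.

    Each class is shuffled once and cut into ten near-equal chunks; fold f
    takes chunk f as test and chunk ``f + folds`` as validation, so test
    partitions never overlap across folds.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    classes = sorted(set(labels.tolist()))
    n_chunks = 10
    if spec.folds * 2 > n_chunks:
        raise ValueError("too many folds for disjoint 10% partitions")
    chunks_by_class = {}
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if len(idx) < n_chunks:
            raise ValueError(
                f"class {c!r} has only {len(idx)} samples; "
                f"at least {n_chunks} are needed for stratified 10% partitions"
            )
        rng.shuffle(idx)
        chunks_by_class[c] = np.array_split(idx, n_chunks)
    folds = []
    for f in range(spec.folds):
        test, val, train = [], [], []
        for c in classes:
            chunks = chunks_by_class[c]
            test.append(chunks[f])
            val.append(chunks[f + spec.folds])
            train.extend(
                chunks[j] for j in range(n_chunks) if j not in (f, f + spec.folds)
            )
        folds.append(
            (
                np.sort(np.concatenate(train)),
                np.sort(np.concatenate(val)),
                np.sort(np.concatenate(test)),
            )
        )
    return folds


def _build_estimator(spec: ClassifierSpec):
    p = dict(spec.params)
    if spec.name == "softmax":
        solver = p.pop("solver", "lbfgs")
        if solver == "sgd":
            est = SGDClassifier(
                loss="log_loss", random_state=spec.seed, **p
            )
        else:
            est = LogisticRegression(
                max_iter=p.pop("max_iter", 2000), random_state=spec.seed, **p
            )
    elif spec.name == "dt":
        est = DecisionTreeClassifier(random_state=spec.seed, **p)
    elif spec.name == "rf":
        est = RandomForestClassifier(
            n_estimators=p.pop("n_estimators", 100), random_state=spec.seed, **p
        )
    elif spec.name == "knn":
        est = KNeighborsClassifier(n_neighbors=p.pop("n_neighbors", 5), **p)
    elif spec.name == "svm":
        est = SVC(kernel="linear", random_state=spec.seed, **p)
    else:  # pragma: no cover - guarded by ClassifierSpec
        raise ValueError(spec.name)
    if spec.name in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    positive_label=POSITIVE_LABEL,
) -> tuple[np.ndarray, np.ndarray]:
    """Train one classifier; return test predictions and positive-class
    scores (probability or decision value, monotone in confidence)."""
    if len(set(np.asarray(y_train).tolist())) < 2:
        raise ValueError("training set must contain both classes")
    est = _build_estimator(spec)
    est.fit(X_train, y_train)
    pred = est.predict(X_test)
    if hasattr(est, "predict_proba"):
        classes = list(est.classes_)
        scores = est.predict_proba(X_test)[:, classes.index(positive_label)]
    else:
        dec = est.decision_function(X_test)
        # decision_function is signed toward classes_[1]
        scores = dec if est.classes_[1] == positive_label else -dec
    return pred, np.asarray(scores, dtype=float)


def run_bench(
    table: FeatureTable,
    specs: list[ClassifierSpec] | None = None,
    split: SplitSpec | None = None,
) -> dict[str, CVResult]:
    """Per classifier, per fold: test-set confusion matrix and metrics."""
    specs = specs if specs is not None else default_specs()
    split = split or SplitSpec()
    folds = make_splits(table.labels, split)
    results: dict[str, CVResult] = {}
    for spec in specs:
        per_fold = []
        for f, (train_idx, _val_idx, test_idx) in enumerate(folds):
            pred, scores = fit_predict(
                spec,
                table.X[train_idx],
                table.labels[train_idx],
                table.X[test_idx],
            )
            cm = confusion(table.labels[test_idx], pred)
            per_fold.append(
                FoldResult(
                    fold=f,
                    cm=cm,
                    report=metrics(cm),
                    scores=scores,
                    test_labels=table.labels[test_idx],
                )
            )
        accs = [fr.report.ac for fr in per_fold]
        results[spec.name] = CVResult(
            classifier=spec.name,
            per_fold=per_fold,
            best_fold=int(np.argmax(accs)),
        )
    return results


def default_specs(seed: int = 0) -> list[ClassifierSpec]:
    return [ClassifierSpec(name=n, seed=seed) for n in CLASSIFIER_NAMES]
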