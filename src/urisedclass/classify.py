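"""Feature-block fusion and the multi-classifier evaluation harness.

Two selected feature blocks (texture and dense) are fused by horizontal
concatenation after verifying row alignment, then classified by one of six
classical classifiers.  Evaluation is either a stratified holdout or
stratified k-fold cross-validation; in CV mode the confusion matrix pools
out-of-fold predictions, so it spans every sample.  Distance- and
margin-based classifiers (SVM, KNN) see features standardized with
train-fold statistics only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .containers import FeatureMatrix, SelectionResult
from .metrics import ConfusionMatrix, confusion_from_labels

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "EvalScheme",
    "subselect",
    "fuse",
    "make_classifier",
    "train_eval",
]

CLASSIFIER_KINDS = (
    "fine_tree",
    "linear_discriminant",
    "gaussian_naive_bayes",
    "svm",
    "knn",
    "ensemble_bagged_trees",
)

# canonical point-and-click defaults for each classifier family
_DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "fine_tree": {"max_splits": 100},
    "linear_discriminant": {"shrinkage": 1e-6},
    "gaussian_naive_bayes": {"var_smoothing": 1e-9},
    "svm": {"kernel": "linear", "C": 1.0},
    "knn": {"n_neighbors": 5},
    "ensemble_bagged_trees": {"n_estimators": 30},
}


@dataclass
class ClassifierSpec:
    """One of the six supported classifiers plus its hyper-parameters."""

    kind: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"kind must be one of {CLASSIFIER_KINDS}")
        allowed = set(_DEFAULT_HYPERPARAMS[self.kind])
        unknown = set(self.hyperparams) - allowed
        if unknown:
            raise ValueError(
                f"unknown hyperparams {sorted(unknown)} for {self.kind}; "
                f"allowed: {sorted(allowed)}"
            )

    def resolved(self) -> dict:
        params = dict(_DEFAULT_HYPERPARAMS[self.kind])
        params.update(self.hyperparams)
        return params


@dataclass
class EvalScheme:
    """Holdout or stratified k-fold evaluation protocol."""

    mode: str = "kfold_cv"
    train_fraction: float = 0.8
    folds: int = 5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("holdout", "kfold_cv"):
            raise ValueError("mode must be 'holdout' or 'kfold_cv'")
        if self.mode == "holdout" and not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.mode == "kfold_cv" and self.folds < 2:
            raise ValueError("folds must be >= 2")


def subselect(matrix: FeatureMatrix, selection: SelectionResult) -> FeatureMatrix:
    """Reorder/keep columns of ``matrix`` per an mRMR selection."""
    idx = selection.selected
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate index in selection")
    for i in idx:
        if not (0 <= i < matrix.n_features):
            raise ValueError(f"selected index {i} out of range for "
                             f"{matrix.n_features} features")
    return FeatureMatrix(
        values=matrix.values[:, idx],
        sample_ids=matrix.sample_ids,
        labels=matrix.labels,
        feature_names=[matrix.feature_names[i] for i in idx],
    )


def fuse(block_a: FeatureMatrix, block_b: FeatureMatrix) -> FeatureMatrix:
    """Horizontally concatenate two row-aligned feature blocks."""
    for i, (a, b) in enumerate(zip(block_a.sample_ids, block_b.sample_ids)):
        if a != b:
            raise ValueError(f"sample_id mismatch at row {i}: '{a}' vs '{b}'")
    if block_a.n_samples != block_b.n_samples:
        raise ValueError("blocks have different sample counts")
    for i, (a, b) in enumerate(zip(block_a.labels, block_b.labels)):
        if a != b:
            raise ValueError(f"label mismatch at row {i}: '{a}' vs '{b}'")
    return FeatureMatrix(
        values=np.hstack([block_a.values, block_b.values]),
        sample_ids=block_a.sample_ids,
        labels=block_a.labels,
        feature_names=block_a.feature_names + block_b.feature_names,
    )


def make_classifier(spec: ClassifierSpec):
    """Build the sklearn estimator (with scaler where appropriate)."""
    p = spec.resolved()
    if spec.kind == "fine_tree":
        return DecisionTreeClassifier(
            criterion="gini", max_leaf_nodes=p["max_splits"] + 1,
            random_state=spec.seed,
        )
    if spec.kind == "linear_discriminant":
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage=p["shrinkage"])
    if spec.kind == "gaussian_naive_bayes":
        return GaussianNB(var_smoothing=p["var_smoothing"])
    if spec.kind == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel=p["kernel"], C=p["C"], random_state=spec.seed)),
        ])
    if spec.kind == "knn":
        return Pipeline([
            ("scale", StandardScaler()),
            ("knn", KNeighborsClassifier(n_neighbors=p["n_neighbors"],
                                         metric="euclidean")),
        ])
    if spec.kind == "ensemble_bagged_trees":
        return BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=spec.seed),
            n_estimators=p["n_estimators"], random_state=spec.seed,
        )
    raise ValueError(spec.kind)  # unreachable; guarded in __post_init__


def train_eval(matrix: FeatureMatrix, classifier: ClassifierSpec,
               scheme: EvalScheme = EvalScheme()
               ) -> tuple[ConfusionMatrix, list[ConfusionMatrix]]:
    """Evaluate one classifier under the scheme; return pooled + per-fold CMs.

    Holdout mode returns the test-fold confusion matrix (fold list holds
    just that matrix); CV mode returns the pooled out-of-fold confusion
    matrix spanning all samples plus the per-fold matrices.
    """
    X = matrix.values
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    class_names = matrix.class_names
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes")
    y = np.asarray(matrix.labels)

    if scheme.mode == "holdout":
        folds = [_holdout_indices(y, scheme)]
    else:
        counts = {c: int((y == c).sum()) for c in class_names}
        too_small = [c for c, n in counts.items() if n < scheme.folds]
        if too_small:
            raise ValueError(
                f"classes {too_small} have fewer samples than folds={scheme.folds}"
            )
        skf = StratifiedKFold(n_splits=scheme.folds, shuffle=True,
                              random_state=scheme.seed)
        folds = list(skf.split(X, y))

    per_fold: list[ConfusionMatrix] = []
    for train_idx, test_idx in folds:
        clf = make_classifier(classifier)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        per_fold.append(confusion_from_labels(y[test_idx], pred, class_names))

    pooled = ConfusionMatrix(
        counts=np.sum([cm.counts for cm in per_fold], axis=0),
        class_names=class_names,
    )
    return pooled, per_fold


def train_eval_nested(blocks: list[FeatureMatrix], k: int,
                      classifier: ClassifierSpec,
                      scheme: EvalScheme = EvalScheme(),
                      criterion: str = "MID", bins: int = 10
                      ) -> tuple[ConfusionMatrix, list[ConfusionMatrix]]:
    """CV with mRMR selection nested inside each training fold.

    Selecting features on the full matrix before cross-validation leaks
    label information into the evaluation (enough to lift pure-noise data
    above chance); this variant re-runs mRMR on each training fold's rows
    of every block, fuses the selected columns, and evaluates on the held
    -out fold, giving an unbiased estimate.
    """
    from .mrmr import mrmr_select

    if scheme.mode != "kfold_cv":
        raise ValueError("nested selection is defined for kfold_cv mode")
    if not blocks:
        raise ValueError("need at least one feature block")
    for b in blocks[1:]:
        if b.sample_ids != blocks[0].sample_ids:
            raise ValueError("blocks must be row-aligned")
    y = np.asarray(blocks[0].labels)
    class_names = blocks[0].class_names
    skf = StratifiedKFold(n_splits=scheme.folds, shuffle=True,
                          random_state=scheme.seed)
    per_fold: list[ConfusionMatrix] = []
    for train_idx, test_idx in skf.split(blocks[0].values, y):
        parts_train, parts_test = [], []
        for block in blocks:
            sub = FeatureMatrix(
                values=block.values[train_idx],
                sample_ids=[block.sample_ids[i] for i in train_idx],
                labels=[block.labels[i] for i in train_idx],
                feature_names=block.feature_names,
            )
            sel = mrmr_select(sub, min(k, block.n_features), criterion, bins)
            parts_train.append(block.values[np.ix_(train_idx, sel.selected)])
            parts_test.append(block.values[np.ix_(test_idx, sel.selected)])
        clf = make_classifier(classifier)
        clf.fit(np.hstack(parts_train), y[train_idx])
        pred = clf.predict(np.hstack(parts_test))
        per_fold.append(confusion_from_labels(y[test_idx], pred, class_names))
    pooled = ConfusionMatrix(
        counts=np.sum([cm.counts for cm in per_fold], axis=0),
        class_names=class_names,
    )
    return pooled, per_fold


def _holdout_indices(y: np.ndarray, scheme: EvalScheme) -> tuple[np.ndarray, np.ndarray]:
    """Stratified holdout via the same rounding rule as dataset splitting."""
    rng = np.random.default_rng(scheme.seed)
    train, test = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if idx.size < 2:
            raise ValueError(f"class '{c}' has fewer than 2 samples")
        perm = rng.permutation(idx.size)
        n_train = int(np.floor(scheme.train_fraction * idx.size + 0.5))
        n_train = min(max(n_train, 1), idx.size - 1)
        train.extend(idx[perm[:n_train]])
        test.extend(idx[perm[n_train:]])
    return np.sort(np.array(train)), np.sort(np.array(test))
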