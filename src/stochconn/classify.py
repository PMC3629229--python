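"""Separability of the two groups in matrix-feature space: vectorization,
PCA projection, linear SVM with leave-one-out cross-validation, and
label-permutation significance of the classifier metrics."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.svm import SVC

from .cohort import CohortDataset

__all__ = [
    "FeatureSet",
    "SvmModel",
    "ConfusionCounts",
    "ClassifierReport",
    "vectorize_matrix",
    "features_from_cohort",
    "pca_projection",
    "svm_train",
    "svm_decision",
    "loocv_evaluate",
    "classification_metrics",
    "label_permutation_significance",
]

#: effectively hard-margin cost for the linear SVM
DEFAULT_SVM_COST = 1e6


@dataclass
class FeatureSet:
    """Subjects x features matrix with two-group labels.

    `positive_label` identifies the patient-like group (counted as the
    positive class in confusion counts)."""

    X: np.ndarray
    labels: np.ndarray
    positive_label: str
    provenance: str = ""  # e.g. "W" or "Q"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or len(self.labels) != self.X.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        uniq = set(self.labels.tolist())
        if len(uniq) != 2:
            raise ValueError(f"exactly two label values required, got {uniq}")
        if self.positive_label not in uniq:
            raise ValueError("positive_label must be one of the label values")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]


@dataclass
class SvmModel:
    """Linear maximal-margin separator; decision value is affine in the
    features."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    bias: float
    estimator: SVC


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class ClassifierReport:
    confusion: ConfusionCounts
    metrics: dict[str, int | None]  # truncated integer percentages
    p_values: dict[str, float | None]
    n_permutations: int
    seed: int | None
    provenance: str = ""


def vectorize_matrix(M: np.ndarray) -> np.ndarray:
    """Reshape a square matrix into a row-major feature vector of length
    N^2."""
    M = np.asarray(M)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("expected a square matrix")
    return M.ravel(order="C").copy()


def features_from_cohort(
    cohort: CohortDataset, source: str = "W", positive_label: str | None = None
) -> FeatureSet:
    """Stack vectorized per-subject matrices (fitted W or empirical Q) into
    a FeatureSet; the case group is the positive class by default."""
    if source not in ("W", "Q"):
        raise ValueError("source must be 'W' or 'Q'")
    rows, labels = [], []
    for sub in cohort.subjects:
        if source == "W":
            if sub.connectivity is None:
                raise ValueError(f"subject {sub.subject_id} has no fitted W")
            rows.append(vectorize_matrix(sub.connectivity.W))
        else:
            if sub.noise is None or sub.noise.Q_empirical is None:
                raise ValueError(f"subject {sub.subject_id} has no fitted Q")
            rows.append(vectorize_matrix(sub.noise.Q_empirical))
        labels.append(sub.group)
    return FeatureSet(
        X=np.vstack(rows),
        labels=np.array(labels),
        positive_label=positive_label or cohort.groups[1],
        provenance=source,
    )


def pca_projection(
    features: FeatureSet | np.ndarray, n_components: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-centered PCA across subjects.

    Returns (coordinates, explained_variance_fractions), components ordered
    by decreasing variance."""
    X = features.X if isinstance(features, FeatureSet) else np.asarray(features, float)
    max_comp = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_comp:
        raise ValueError(f"n_components must be <= {max_comp}")
    pca = PCA(n_components=n_components)
    coords = pca.fit_transform(X)
    return coords, pca.explained_variance_ratio_


def svm_train(X: np.ndarray, y: np.ndarray, cost: float = DEFAULT_SVM_COST) -> SvmModel:
    """Fit the linear (dot-product kernel) support-vector classifier."""
    if len(set(np.asarray(y).tolist())) < 2:
        raise ValueError("training data must contain two classes")
    # max_iter cap: at near-hard-margin cost, libsvm converges very slowly
    # on non-separable (e.g. permuted-label) folds; the cap bounds runtime
    # without affecting separable fits
    est = SVC(kernel="linear", C=cost, max_iter=10_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(np.asarray(X, float), np.asarray(y))
    return SvmModel(
        support_vectors=est.support_vectors_,
        dual_coef=est.dual_coef_,
        bias=float(est.intercept_[0]),
        estimator=est,
    )


def svm_decision(model: SvmModel, x: np.ndarray) -> np.ndarray:
    """Signed distance-like decision values for one or more feature rows."""
    x = np.atleast_2d(np.asarray(x, float))
    return model.estimator.decision_function(x)


def _loocv_counts(
    X: np.ndarray,
    labels: np.ndarray,
    positive_label: str,
    cost: float,
) -> ConfusionCounts:
    tp = fn = tn = fp = 0
    n = len(labels)
    for held in range(n):
        mask = np.ones(n, bool)
        mask[held] = False
        train_labels = labels[mask]
        truth_pos = labels[held] == positive_label
        if len(set(train_labels.tolist())) < 2:
            # untrainable fold: held-out subject counts as misclassified
            if truth_pos:
                fn += 1
            else:
                fp += 1
            continue
        model = svm_train(X[mask], train_labels, cost=cost)
        pred = model.estimator.predict(X[held : held + 1])[0]
        pred_pos = pred == positive_label
        if truth_pos and pred_pos:
            tp += 1
        elif truth_pos:
            fn += 1
        elif pred_pos:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)


def loocv_evaluate(
    features: FeatureSet, cost: float = DEFAULT_SVM_COST
) -> ConfusionCounts:
    """Leave-one-out cross-validation: train on all subjects but one,
    classify the held-out subject, accumulate confusion counts with the
    patient group as positive."""
    labels = features.labels
    pos = features.positive_label
    n_pos = int(np.sum(labels == pos))
    n_neg = len(labels) - n_pos
    if min(n_pos, n_neg) < 3:
        warnings.warn(
            "fewer than 3 subjects in a class; LOOCV estimates are unreliable",
            RuntimeWarning,
            stacklevel=2,
        )
    return _loocv_counts(features.X, labels, pos, cost)


def classification_metrics(confusion: ConfusionCounts) -> dict[str, int | None]:
    """Accuracy, specificity, sensitivity and F-score as integer percents
    truncated toward zero (16/19 -> 84).  F-score is None when precision is
    undefined (no positive predictions)."""
    tp, fn, tn, fp = confusion.tp, confusion.fn, confusion.tn, confusion.fp
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("confusion counts must be nonnegative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both class totals must be positive")
    accuracy = (tp + tn) / confusion.total
    sensitivity = tp / (tp + fn)
    specificity = tn / (tn + fp)
    if tp + fp == 0:
        f_score = None
    else:
        precision = tp / (tp + fp)
        f_score = (
            0.0
            if precision + sensitivity == 0
            else 2 * precision * sensitivity / (precision + sensitivity)
        )
    trunc = lambda v: None if v is None else int(math.trunc(100 * v))
    return {
        "accuracy": trunc(accuracy),
        "specificity": trunc(specificity),
        "sensitivity": trunc(sensitivity),
        "f_score": trunc(f_score),
    }


def label_permutation_significance(
    features: FeatureSet,
    n_perm: int = 10_000,
    seed: int | None = 0,
    cost: float = DEFAULT_SVM_COST,
) -> ClassifierReport:
    """Observed LOOCV metrics plus per-metric permutation p-values.

    The full LOOCV is repeated under random label permutations; each
    p-value is the fraction of permuted runs whose metric is greater than
    or equal to the observed one.  With `n_perm` = 0 the p-values are
    reported as unavailable (None).
    """
    confusion = loocv_evaluate(features, cost=cost)
    observed = classification_metrics(confusion)
    names = ["accuracy", "specificity", "sensitivity", "f_score"]
    if n_perm <= 0:
        pvals = {k: None for k in names}
        return ClassifierReport(confusion, observed, pvals, 0, seed, features.provenance)
    rng = np.random.default_rng(seed)
    counts = {k: 0 for k in names}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_perm):
            perm_labels = rng.permutation(features.labels)
            if len(set(perm_labels.tolist())) < 2:
                continue
            conf = _loocv_counts(features.X, perm_labels, features.positive_label, cost)
            met = classification_metrics(conf)
            for k in names:
                obs, val = observed[k], met[k]
                if obs is None:
                    continue
                if val is not None and val >= obs:
                    counts[k] += 1
    pvals = {
        k: (None if observed[k] is None else counts[k] / n_perm) for k in names
    }
    return ClassifierReport(
        confusion=confusion,
        metrics=observed,
        p_values=pvals,
        n_permutations=n_perm,
        seed=seed,
        provenance=features.provenance,
    )
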