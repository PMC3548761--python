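"""Soft-margin RBF-kernel classification of encoded peptides, the standard
binding-prediction performance metrics, and repeated stratified
cross-validation.

The classifier contract is: cost parameter C = 1, radial basis kernel,
features standardised with statistics learned on the training fold only,
continuous decision values (higher = more binder-like), hard calls at
score > 0. The kernel width defaults to the median-pairwise-distance
heuristic on the (standardised) training data. An ``epsilon`` setting is
accepted for interface compatibility with regression-capable SVM packages
and ignored in classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import joblib
import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


class TrainingError(ValueError):
    pass


@dataclass(frozen=True)
class ClassifierSpec:
    cost: float = 1.0
    kernel: str = "rbf"
    kernel_width_mode: str = "median_heuristic"  # or "fixed"
    kernel_width: float | None = None  # gamma, required iff mode == "fixed"
    standardize_features: bool = True
    epsilon: float = 0.1  # accepted, ignored for classification
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cost <= 0:
            raise TrainingError("cost must be positive")
        if self.kernel != "rbf":
            raise TrainingError("only the RBF kernel is supported")
        if self.kernel_width_mode not in ("median_heuristic", "fixed"):
            raise TrainingError(f"unknown kernel_width_mode {self.kernel_width_mode!r}")
        if (self.kernel_width is not None) != (self.kernel_width_mode == "fixed"):
            raise TrainingError("kernel_width must be given iff kernel_width_mode='fixed'")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sens: float
    spec: float
    f1: float
    auc: float | None = None


@dataclass(frozen=True)
class CvResult:
    per_iteration_auc: list[float]
    fold_count: int
    iteration_count: int
    seed: int

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.per_iteration_auc))

    @property
    def sd_auc(self) -> float:
        if len(self.per_iteration_auc) < 2:
            return 0.0
        return float(np.std(self.per_iteration_auc, ddof=1))


class TrainedModel:
    """A fitted classifier plus the standardisation learned from its training data."""

    def __init__(self, spec: ClassifierSpec, svc: SVC, mean: np.ndarray, scale: np.ndarray):
        self.spec = spec
        self._svc = svc
        self._mean = mean
        self._scale = scale

    @property
    def n_features(self) -> int:
        return len(self._mean)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {X.shape[1]}")
        return self._svc.decision_function((X - self._mean) / self._scale)

    def predict(self, X: np.ndarray, threshold: float = 0.0) -> np.ndarray:
        return (self.decision_scores(X) > threshold).astype(int)

    def save(self, path) -> None:
        joblib.dump(
            {"format": "epiccapo-model", "version": 1, "spec": self.spec,
             "svc": self._svc, "mean": self._mean, "scale": self._scale},
            path,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        blob = joblib.load(path)
        if blob.get("format") != "epiccapo-model":
            raise ValueError(f"{path}: not a model file")
        return cls(blob["spec"], blob["svc"], blob["mean"], blob["scale"])


def _median_heuristic_gamma(X: np.ndarray, seed: int, max_points: int = 512) -> float:
    """gamma = 1 / (2 * median^2) of pairwise Euclidean distances.

    Subsamples deterministically above ``max_points`` to keep the O(n^2)
    distance computation bounded.
    """
    n = len(X)
    if n > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(n, max_points, replace=False)]
    from scipy.spatial.distance import pdist

    d = pdist(X)
    d = d[d > 0]
    if len(d) == 0:  # all points identical; any width works
        return 1.0 / X.shape[1]
    med = float(np.median(d))
    return 1.0 / (2.0 * med * med)


def fit_classifier(X: np.ndarray, y: np.ndarray, spec: ClassifierSpec) -> TrainedModel:
    """Fit the RBF-kernel classifier; deterministic given (X, y, spec.seed)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise TrainingError(f"bad shapes X {X.shape}, y {y.shape}")
    if not np.all(np.isfinite(X)):
        raise TrainingError("X contains non-finite features")
    classes = np.unique(y)
    if len(classes) < 2:
        raise TrainingError("training data contains a single class")
    if spec.epsilon != 0.1:
        logger.info("epsilon=%s has no effect in classification mode", spec.epsilon)

    if spec.standardize_features:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        mean = np.zeros(X.shape[1])
        scale = np.ones(X.shape[1])
    Xs = (X - mean) / scale

    if spec.kernel_width_mode == "fixed":
        gamma = spec.kernel_width
    else:
        gamma = _median_heuristic_gamma(Xs, seed=spec.seed)
    svc = SVC(C=spec.cost, kernel="rbf", gamma=gamma, random_state=spec.seed)
    svc.fit(Xs, y)
    return TrainedModel(spec=spec, svc=svc, mean=mean, scale=scale)


def decision_scores(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.decision_scores(X)


def confusion(y_true: Sequence[int], scores: Sequence[float], threshold: float = 0.0) -> ConfusionCounts:
    """Count TP/FP/TN/FN by comparing score > threshold against binary truth."""
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(y) == 0:
        raise ValueError("empty input")
    if len(y) != len(s):
        raise ValueError("y_true and scores differ in length")
    pred = s > threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def compute_metrics(c: ConfusionCounts, auc_value: float | None = None) -> MetricSet:
    """ACC, sensitivity, specificity and F1 from the confusion counts.

    ACC  = (TP + TN) / (TP + TN + FP + FN)
    sens = TP / (TP + FN)
    spec = TN / (FP + TN)
    F1   = 2 TP / (2 TP + FN + FP)

    Undefined denominators (no positives for sens, no negatives for spec)
    raise rather than silently reporting 0.
    """
    if c.total == 0:
        raise ValueError("no evaluated records")
    if c.tp + c.fn == 0:
        raise ValueError("sensitivity undefined: no positive records")
    if c.fp + c.tn == 0:
        raise ValueError("specificity undefined: no negative records")
    return MetricSet(
        acc=(c.tp + c.tn) / c.total,
        sens=c.tp / (c.tp + c.fn),
        spec=c.tn / (c.fp + c.tn),
        f1=2 * c.tp / (2 * c.tp + c.fn + c.fp),
        auc=auc_value,
    )


def auc(y_true: Sequence[int], scores: Sequence[float]) -> float:
    """Rank-based (Mann-Whitney) ROC AUC; tied scores contribute 1/2."""
    y = np.asarray(y_true, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: a single class present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _iteration_seed(seed: int, iteration: int) -> int:
    return (seed * 100_003 + 7919 * iteration + 1) % (2**31 - 1)


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    folds: int = 5,
    iterations: int = 20,
    seed: int = 0,
) -> CvResult:
    """Repeated stratified k-fold CV.

    Each iteration draws a fresh stratified partition seeded by (seed,
    iteration), pools the out-of-fold decision scores, and records one AUC;
    the result carries the per-iteration AUCs and their mean/sd. Feature
    standardisation (and anything else learned) happens inside each training
    fold only, via fit_classifier.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) < folds:
        raise TrainingError(f"n={len(X)} < folds={folds}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise TrainingError(f"smallest class has {counts.min()} members; cannot stratify into {folds} folds")
    per_iter: list[float] = []
    for it in range(iterations):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=_iteration_seed(seed, it))
        oof = np.empty(len(y))
        for train_idx, test_idx in skf.split(X, y):
            model = fit_classifier(X[train_idx], y[train_idx], replace(spec, seed=_iteration_seed(seed, it)))
            oof[test_idx] = model.decision_scores(X[test_idx])
        per_iter.append(auc(y, oof))
    return CvResult(per_iteration_auc=per_iter, fold_count=folds, iteration_count=iterations, seed=seed)


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    degenerate: bool = False


def paired_ttest(auc_a: Sequence[float], auc_b: Sequence[float], tails: str = "two") -> TTestResult:
    """Classical paired t-test on matched AUC lists.

    Zero-variance differences are handled by convention: equal means give
    p = 1; unequal means give the p -> 0 limit, flagged as degenerate.
    ``tails='one'`` tests the alternative mean(a) > mean(b).
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("need two equal-length lists of length >= 2")
    if tails not in ("one", "two"):
        raise ValueError(f"tails must be 'one' or 'two', got {tails!r}")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if d.mean() == 0:
            return TTestResult(t=0.0, p=1.0, degenerate=True)
        return TTestResult(t=float(np.inf) * np.sign(d.mean()), p=0.0, degenerate=True)
    alternative = "two-sided" if tails == "two" else "greater"
    res = stats.ttest_rel(a, b, alternative=alternative)
    return TTestResult(t=float(res.statistic), p=float(res.pvalue))
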