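"""Feature selection: greedy contact-potential subset search and Relief-F
prefix feature selection.

Two procedures sit on top of the encoded datasets:

* potential-subset selection — each of the K potentials contributes a
  9-column block; blocks are ranked by their solo cross-validated AUC, then
  prefixes of the ranking are evaluated (all with one fixed CV seed so the
  curves differ only by features) and the best prefix is kept;
* Relief-F prefix selection — features are weighted by a Weka-dialect
  Relief-F (k = 10 nearest hits/misses, all instances sampled, Manhattan
  neighbour distance on range-normalised features), averaged over the
  training folds of a 5-fold split, ranked, and the AUC-maximising prefix
  of the ranking is kept. Argmax ties always take the shorter prefix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import ClassifierSpec, CvResult, TrainingError, cross_validate

M = 9  # positions per potential block


@dataclass(frozen=True)
class AappRanking:
    """Potentials ordered by solo AUC descending, ties broken by id ascending."""

    entries: list[tuple[str, float]]

    @property
    def ids(self) -> list[str]:
        return [e[0] for e in self.entries]


@dataclass(frozen=True)
class AappSubsetResult:
    prefix_aucs: list[float]
    selected_ids: list[str]
    selected_auc: float


@dataclass(frozen=True)
class FeatureRanking:
    weights: np.ndarray
    order: np.ndarray  # feature indices, best first
    fold_count: int = 1


@dataclass(frozen=True)
class FeatureSubsetResult:
    prefix_aucs: list[float]
    selected_count: int
    selected_auc: float

    @property
    def selected_features(self) -> int:
        return self.selected_count


def _block_columns(k: int) -> slice:
    """0-based column slice of potential block ``k`` (0-based) in the capo layout."""
    return slice(M * k, M * (k + 1))


def per_aapp_auc(
    X: np.ndarray,
    y: np.ndarray,
    aapp_ids: Sequence[str],
    cvspec: ClassifierSpec,
    folds: int = 5,
    iterations: int = 1,
    seed: int = 0,
) -> AappRanking:
    """Solo cross-validated AUC of each potential's 9-column block.

    ``X`` must be in the capo layout: columns 9k..9k+8 belong to potential k.
    """
    X = np.asarray(X, dtype=float)
    K = len(aapp_ids)
    if X.shape[1] != M * K:
        raise ValueError(f"X has {X.shape[1]} columns, expected {M * K} for {K} potentials")
    entries = []
    for k, aapp_id in enumerate(aapp_ids):
        cv = cross_validate(X[:, _block_columns(k)], y, cvspec, folds=folds, iterations=iterations, seed=seed)
        entries.append((str(aapp_id), cv.mean_auc))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return AappRanking(entries=entries)


def greedy_aapp_subset(
    X: np.ndarray,
    y: np.ndarray,
    aapp_ids: Sequence[str],
    ranking: AappRanking,
    cvspec: ClassifierSpec,
    folds: int = 5,
    iterations: int = 1,
    seed: int = 0,
) -> AappSubsetResult:
    """Evaluate every prefix of the ranking with one fixed CV seed; keep the argmax.

    Ties select the shortest prefix.
    """
    ids = list(map(str, aapp_ids))
    if sorted(ranking.ids) != sorted(ids):
        raise ValueError("ranking does not cover exactly the provided potentials")
    col_of = {a: k for k, a in enumerate(ids)}
    prefix_aucs: list[float] = []
    for plen in range(1, len(ids) + 1):
        cols = np.concatenate(
            [np.arange(M * col_of[a], M * col_of[a] + M) for a in ranking.ids[:plen]]
        )
        cv = cross_validate(X[:, cols], y, cvspec, folds=folds, iterations=iterations, seed=seed)
        prefix_aucs.append(cv.mean_auc)
    best = int(np.argmax(prefix_aucs))  # np.argmax returns the first (smallest) maximiser
    return AappSubsetResult(
        prefix_aucs=prefix_aucs,
        selected_ids=ranking.ids[: best + 1],
        selected_auc=prefix_aucs[best],
    )


def relieff_weights(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 10,
    sample_size: int | None = None,
    seed: int = 0,
) -> FeatureRanking:
    """Relief-F feature weights, Weka dialect.

    For each sampled record R (default: every record, in index order), the k
    nearest same-class hits and, per other class C, the k nearest misses are
    found by Manhattan distance on range-normalised features (ties broken by
    record index). Weights update as

        W[f] -= diff(f, R, hit) / (m k)
        W[f] += P(C) / (1 - P(class(R))) * diff(f, R, miss) / (m k)

    with diff(f, x1, x2) = |x1_f - x2_f| / (max_f - min_f). Constant features
    (zero range) get weight exactly 0.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, n_feat = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k_neighbors + 1:
        raise TrainingError(
            f"smallest class has {counts.min()} records; Relief-F with k={k_neighbors} "
            f"needs at least {k_neighbors + 1} per class (reduce k_neighbors)"
        )
    rng_span = X.max(axis=0) - X.min(axis=0)
    active = rng_span > 0
    Xn = np.zeros_like(X)
    Xn[:, active] = X[:, active] / rng_span[active]  # per-feature diffs in [0,1]

    prior = {c: cnt / n for c, cnt in zip(classes, counts)}
    if sample_size is None or sample_size >= n:
        sample = np.arange(n)
    else:
        sample = np.sort(np.random.default_rng(seed).choice(n, sample_size, replace=False))
    m = len(sample)

    # neighbour search per class; ties in distance broken by record index via
    # lexicographic sort on (distance, index)
    idx_by_class = {c: np.flatnonzero(y == c) for c in classes}
    W = np.zeros(n_feat)
    for r in sample:
        xr = Xn[r]
        for c in classes:
            members = idx_by_class[c]
            cand = members[members != r]
            d = np.abs(Xn[cand] - xr).sum(axis=1)
            order = np.lexsort((cand, d))[:k_neighbors]
            neigh = cand[order]
            diffsum = np.abs(Xn[neigh] - xr).sum(axis=0)
            if c == y[r]:
                W -= diffsum / (m * k_neighbors)
            else:
                W += (prior[c] / (1.0 - prior[y[r]])) * diffsum / (m * k_neighbors)
    W[~active] = 0.0
    order = np.lexsort((np.arange(n_feat), -W))
    return FeatureRanking(weights=W, order=order, fold_count=1)


def cv_relieff_rank(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    k_neighbors: int = 10,
    seed: int = 0,
) -> FeatureRanking:
    """Average Relief-F weights over the training folds of a stratified split."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31 - 1))
    weight_sum = np.zeros(X.shape[1])
    for train_idx, _ in skf.split(X, y):
        fr = relieff_weights(X[train_idx], y[train_idx], k_neighbors=k_neighbors, seed=seed)
        weight_sum += fr.weights
    weights = weight_sum / folds
    order = np.lexsort((np.arange(X.shape[1]), -weights))
    return FeatureRanking(weights=weights, order=order, fold_count=folds)


def prefix_feature_select(
    X: np.ndarray,
    y: np.ndarray,
    ranking: FeatureRanking,
    cvspec: ClassifierSpec,
    folds: int = 5,
    iterations: int = 1,
    seed: int = 0,
) -> FeatureSubsetResult:
    """CV AUC of every prefix of the feature ranking; keep the smallest argmax."""
    X = np.asarray(X, dtype=float)
    if len(ranking.order) != X.shape[1]:
        raise ValueError("ranking does not cover all features")
    prefix_aucs: list[float] = []
    for plen in range(1, X.shape[1] + 1):
        cols = ranking.order[:plen]
        cv = cross_validate(X[:, cols], y, cvspec, folds=folds, iterations=iterations, seed=seed)
        prefix_aucs.append(cv.mean_auc)
    best = int(np.argmax(prefix_aucs))
    return FeatureSubsetResult(
        prefix_aucs=prefix_aucs, selected_count=best + 1, selected_auc=prefix_aucs[best]
    )
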