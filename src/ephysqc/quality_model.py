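"""Linear-SVM quality classification with exhaustive wrapper feature
selection, voting ensembles and the bias-free two-stage leave-one-out
evaluation.

Conventions:

* the SVM is a linear one-vs-one machine with C = 512 and a 1e4 iteration
  cap; non-convergence is logged and the model used anyway;
* features are z-scored with statistics fitted on the training portion of
  each fold only (zero-variance columns pass through with scale 1);
* feature subsets are identified by their size and 0-based lexicographic
  rank, e.g. "6-2133";
* all ties (equal CV means, equal votes) break deterministically: lower
  canonical rank first / best-ranked ensemble member first.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, floor
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import SVC

log = logging.getLogger(__name__)

__all__ = [
    "SVMConfig",
    "Scaler",
    "standardize",
    "train_svm",
    "predict",
    "CVResult",
    "WrapperResult",
    "repeated_kfold_cv",
    "loo_cv",
    "wrapper_search",
    "top10_group",
    "vote_predict",
    "two_fold_loo",
    "cross_dataset_eval",
    "merge_classes",
    "prediction_correlation",
    "enumerate_feature_sets",
    "subset_rank",
    "canonical_name",
    "consistency_histogram",
    "QualityModel",
    "model_to_dict",
    "model_from_dict",
]


@dataclass(frozen=True)
class SVMConfig:
    """Classifier constants."""

    C: float = 512.0
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


DEFAULT_CONFIG = SVMConfig()


# ---------------------------------------------------------------------------
# feature-subset bookkeeping

def enumerate_feature_sets(
    n_features: int = 16, sizes: Iterable[int] | None = None
) -> Iterator[tuple[int, ...]]:
    """Yield every feature subset (0-based, sorted tuples) of the requested
    sizes in lexicographic order; all sizes 1..n_features by default."""
    sizes = range(1, n_features + 1) if sizes is None else sizes
    for size in sizes:
        yield from combinations(range(n_features), size)


def subset_rank(subset: Sequence[int], n_features: int = 16) -> int:
    """0-based lexicographic rank of ``subset`` among subsets of its size
    (combinatorial number system)."""
    fs = tuple(subset)
    k = len(fs)
    rank = 0
    prev = -1
    for pos, c in enumerate(fs):
        for skipped in range(prev + 1, c):
            rank += comb(n_features - skipped - 1, k - pos - 1)
        prev = c
    return rank


def canonical_name(subset: Sequence[int], n_features: int = 16) -> str:
    """'size-rank' label of a feature set, e.g. '6-2133'."""
    return f"{len(subset)}-{subset_rank(subset, n_features)}"


# ---------------------------------------------------------------------------
# scaling and the SVM

@dataclass
class Scaler:
    """Per-feature location/scale fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


def standardize(X: np.ndarray) -> Scaler:
    """Fit a z-scoring scaler; zero-variance columns get scale 1."""
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale == 0, 1.0, scale)
    return Scaler(mean=mean, scale=scale)


class _ConstantModel:
    """Fallback for single-class training sets."""

    def __init__(self, label) -> None:
        self.label = label
        self.classes_ = np.array([label])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.label)


@dataclass
class QualityModel:
    """A trained classifier: feature subset + scaler + linear SVM."""

    feature_set: tuple[int, ...]
    scaler: Scaler
    clf: object
    config: SVMConfig = field(default_factory=SVMConfig)

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = np.asarray(X, dtype=float)[:, self.feature_set]
        return self.clf.predict(self.scaler.apply(Xs))


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig = DEFAULT_CONFIG,
    feature_set: Sequence[int] | None = None,
) -> QualityModel:
    """Train a standardised linear one-vs-one SVM on (a feature subset of) X.

    A single-class training set yields a constant model (logged).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    fs = tuple(range(X.shape[1])) if feature_set is None else tuple(feature_set)
    Xs = X[:, fs]
    scaler = standardize(Xs)
    classes = np.unique(y)
    if classes.size < 2:
        log.debug("single-class training set; using constant model")
        return QualityModel(fs, scaler, _ConstantModel(classes[0]), config)
    clf = SVC(kernel="linear", C=config.C, max_iter=config.max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(scaler.apply(Xs), y)
    return QualityModel(fs, scaler, clf, config)


def predict(model: QualityModel, X: np.ndarray) -> np.ndarray:
    return model.predict(X)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    """Cross-validation performance of one feature subset."""

    feature_set: tuple[int, ...]
    fraction_correct: np.ndarray  # one value per repeat

    @property
    def mean(self) -> float:
        return float(np.mean(self.fraction_correct))

    def rank_key(self, n_features: int = 16) -> tuple:
        """Sort key: higher mean first, ties by size then canonical rank."""
        return (-self.mean, len(self.feature_set),
                subset_rank(self.feature_set, n_features))


def _kfold_indices(
    n: int, k: int, rng: np.random.Generator, y: np.ndarray | None = None
) -> list[np.ndarray]:
    """Random partition into k near-equal folds; exhaustive over samples.

    With ``y`` given, folds are stratified per class (optional mode).
    """
    if y is None:
        return [f for f in np.array_split(rng.permutation(n), k)]
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for cls in np.unique(y):
        idx = rng.permutation(np.nonzero(y == cls)[0])
        for j, i in enumerate(idx):
            folds[(start + j) % k].append(int(i))
        start += idx.size
    return [np.asarray(sorted(f), dtype=int) for f in folds]


def repeated_kfold_cv(
    X: np.ndarray,
    y: np.ndarray,
    feature_set: Sequence[int] | None = None,
    k: int = 10,
    repeats: int = 50,
    config: SVMConfig = DEFAULT_CONFIG,
    seed=0,
    stratified: bool = False,
    return_predictions: bool = False,
):
    """Repeated random k-fold cross-validation of one feature subset.

    Each repeat partitions the data into k near-equal random folds (every
    sample left out exactly once), trains on k-1 folds and scores the rest;
    the per-repeat value is the fraction of correct predictions over all n
    samples. Deterministic under ``seed``. With ``return_predictions`` the
    held-out predictions (repeats x n) are returned alongside the result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    fs = tuple(range(X.shape[1])) if feature_set is None else tuple(feature_set)
    Xs = X[:, fs]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    fractions = np.empty(repeats)
    predictions = np.empty((repeats, n), dtype=y.dtype)
    for rep in range(repeats):
        folds = _kfold_indices(n, k, rng, y if stratified else None)
        for fold in folds:
            if fold.size == 0:
                continue
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            model = train_svm(Xs[mask], y[mask], config)
            predictions[rep, fold] = model.predict(Xs[fold])
        fractions[rep] = float(np.mean(predictions[rep] == y))
    result = CVResult(feature_set=fs, fraction_correct=fractions)
    if return_predictions:
        return result, predictions
    return result


def loo_cv(
    X: np.ndarray,
    y: np.ndarray,
    feature_set: Sequence[int] | None = None,
    config: SVMConfig = DEFAULT_CONFIG,
) -> CVResult:
    """Leave-one-out cross-validation (deterministic, no RNG)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    fs = tuple(range(X.shape[1])) if feature_set is None else tuple(feature_set)
    Xs = X[:, fs]
    correct = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        model = train_svm(Xs[mask], y[mask], config)
        correct += int(model.predict(Xs[i : i + 1])[0] == y[i])
    return CVResult(feature_set=fs, fraction_correct=np.array([correct / n]))


# ---------------------------------------------------------------------------
# wrapper feature selection

def top10_group(results: Sequence[CVResult], n_features: int = 16) -> list[CVResult]:
    """The best-performing subsets of one size: 10 of them, or the best 10%
    when fewer than 100 exist, but always at least one.

    m = min(10, max(1, floor(0.1 * N))); ties break by canonical rank.
    """
    if not results:
        raise ValueError("no CV results")
    m = min(10, max(1, floor(0.1 * len(results))))
    ordered = sorted(results, key=lambda r: r.rank_key(n_features))
    return ordered[:m]


@dataclass
class WrapperResult:
    """All per-subset CV results of a wrapper search, grouped by size."""

    results: dict[int, list[CVResult]]
    n_features: int = 16

    def best(self, size: int) -> CVResult:
        return min(self.results[size], key=lambda r: r.rank_key(self.n_features))

    def worst(self, size: int) -> CVResult:
        return min(self.results[size],
                   key=lambda r: (r.mean,
                                  subset_rank(r.feature_set, self.n_features)))

    def median_score(self, size: int) -> float:
        return float(np.median([r.mean for r in self.results[size]]))

    def top10(self, size: int) -> list[CVResult]:
        return top10_group(self.results[size], self.n_features)

    def top10_mean(self, size: int) -> float:
        return float(np.mean([r.mean for r in self.top10(size)]))

    def summary(self) -> pd.DataFrame:
        rows = []
        for size in sorted(self.results):
            rows.append({
                "size": size,
                "n_subsets": len(self.results[size]),
                "best": self.best(size).mean,
                "best_set": canonical_name(self.best(size).feature_set,
                                           self.n_features),
                "worst": self.worst(size).mean,
                "median": self.median_score(size),
                "top10_mean": self.top10_mean(size),
            })
        return pd.DataFrame(rows).set_index("size")

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "results": {
                str(size): [
                    {"feature_set": list(r.feature_set),
                     "fraction_correct": [float(x) for x in r.fraction_correct]}
                    for r in res
                ]
                for size, res in self.results.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WrapperResult":
        results = {
            int(size): [
                CVResult(tuple(r["feature_set"]),
                         np.asarray(r["fraction_correct"], dtype=float))
                for r in res
            ]
            for size, res in d["results"].items()
        }
        return cls(results=results, n_features=int(d["n_features"]))


def wrapper_search(
    X: np.ndarray,
    y: np.ndarray,
    sizes: Iterable[int] | None = None,
    config: SVMConfig = DEFAULT_CONFIG,
    seed: int = 0,
    repeats: int = 50,
    k: int = 10,
    stratified: bool = False,
) -> WrapperResult:
    """Brute-force evaluation of every feature subset of the given sizes.

    Each subset is scored by ``repeated_kfold_cv`` with a seed derived
    deterministically from (seed, size, rank), so results are reproducible
    and independent of evaluation order. Over all 16 sizes this enumerates
    2^16 - 1 = 65,535 subsets; pass reduced ``sizes``/``repeats`` for
    desk-scale runs.
    """
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    sizes = list(range(1, n_features + 1) if sizes is None else sizes)
    results: dict[int, list[CVResult]] = {}
    for size in sizes:
        per_size: list[CVResult] = []
        for rank, fs in enumerate(combinations(range(n_features), size)):
            res = repeated_kfold_cv(
                X, y, feature_set=fs, k=k, repeats=repeats, config=config,
                seed=[seed, size, rank], stratified=stratified,
            )
            per_size.append(res)
        results[size] = per_size
    return WrapperResult(results=results, n_features=n_features)


# ---------------------------------------------------------------------------
# ensembles and evaluation procedures

def vote_predict(models: Sequence[QualityModel], X: np.ndarray) -> np.ndarray:
    """Majority vote over ensemble members ordered best-CV-rank first.

    Vote ties go to the best-ranked member whose prediction is among the
    tied labels.
    """
    if not models:
        raise ValueError("empty ensemble")
    votes = np.stack([m.predict(X) for m in models])  # members x samples
    out = np.empty(votes.shape[1], dtype=votes.dtype)
    for j in range(votes.shape[1]):
        labels, counts = np.unique(votes[:, j], return_counts=True)
        tied = set(labels[counts == counts.max()])
        if len(tied) == 1:
            out[j] = tied.pop()
        else:
            out[j] = next(v for v in votes[:, j] if v in tied)
    return out


def merge_classes(y: np.ndarray) -> np.ndarray:
    """Collapse to 2 classes: good (+1) vs unacceptable (-1, pooling
    intermediate and bad)."""
    y = np.asarray(y)
    return np.where(y == 1, 1, -1)


def prediction_correlation(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Pearson correlation of two -1/0/+1 prediction vectors; NaN if either
    vector is constant."""
    a = np.asarray(labels_a, dtype=float)
    b = np.asarray(labels_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def two_fold_loo(
    X: np.ndarray,
    y: np.ndarray,
    config: SVMConfig = DEFAULT_CONFIG,
    sizes: Iterable[int] | None = None,
    m: int = 10,
    mode: str = "pooled",
) -> dict:
    """Two-stage leave-one-out evaluation of the full wrapper pipeline.

    For every left-out recording: run a wrapper search with leave-one-out CV
    on the remaining n-1 recordings, select the ``m`` best feature sets
    (pooled across sizes when ``mode='pooled'``, or the top10 of each size
    when ``mode='per_size'``), train each on all n-1 recordings, and predict
    the held-out recording individually and by majority vote. The held-out
    recording never influences feature choice or training; a checksum of
    the inner training ids per outer fold witnesses this.

    Returns a dict with vote predictions, the member-prediction matrix,
    per-recording consistency (fraction of ensemble members correct),
    overall vote accuracy, chosen feature sets and the checksums.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 recordings")
    n_features = X.shape[1]
    sizes = list(range(1, n_features + 1) if sizes is None else sizes)

    vote_pred = np.empty(n, dtype=y.dtype)
    member_pred: list[np.ndarray] = []
    consistency = np.empty(n)
    chosen: list[list[tuple[int, ...]]] = []
    checksums: list[str] = []

    all_subsets = [fs for fs in enumerate_feature_sets(n_features, sizes)]
    for i in range(n):
        train_idx = np.array([j for j in range(n) if j != i])
        checksums.append(
            hashlib.sha256(train_idx.tobytes()).hexdigest()
        )
        Xtr, ytr = X[train_idx], y[train_idx]
        inner = [loo_cv(Xtr, ytr, feature_set=fs, config=config)
                 for fs in all_subsets]
        if mode == "pooled":
            selected = sorted(inner, key=lambda r: r.rank_key(n_features))[:m]
        elif mode == "per_size":
            selected = []
            for size in sizes:
                selected.extend(top10_group(
                    [r for r in inner if len(r.feature_set) == size],
                    n_features))
        else:
            raise ValueError(f"unknown mode {mode!r}")
        models = [train_svm(Xtr, ytr, config, feature_set=r.feature_set)
                  for r in selected]
        preds = np.array([mod.predict(X[i : i + 1])[0] for mod in models])
        member_pred.append(preds)
        consistency[i] = float(np.mean(preds == y[i]))
        vote_pred[i] = vote_predict(models, X[i : i + 1])[0]
        chosen.append([r.feature_set for r in selected])

    return {
        "vote_predictions": vote_pred,
        "member_predictions": member_pred,
        "consistency": consistency,
        "vote_accuracy": float(np.mean(vote_pred == y)),
        "chosen_feature_sets": chosen,
        "train_checksums": checksums,
    }


def consistency_histogram(consistency: np.ndarray, bins: int = 11) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of per-recording fractions of correct ensemble members."""
    counts, edges = np.histogram(np.asarray(consistency), bins=bins, range=(0.0, 1.0))
    return counts, edges


class _LinearOvO:
    """Linear one-vs-one predictor rebuilt from serialized weights.

    Replays libsvm's pairwise vote: pair (i, j) votes i when its decision
    value is positive; vote ties break by the larger cumulative decision
    sum, then by class order.
    """

    def __init__(self, classes: np.ndarray, coef: np.ndarray, intercept: np.ndarray):
        self.classes_ = np.asarray(classes)
        self.coef_ = np.asarray(coef, dtype=float)
        self.intercept_ = np.asarray(intercept, dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        k = len(self.classes_)
        dec = X @ self.coef_.T + self.intercept_  # n x n_pairs
        votes = np.zeros((X.shape[0], k))
        margins = np.zeros((X.shape[0], k))
        pair = 0
        for i in range(k):
            for j in range(i + 1, k):
                d = dec[:, pair]
                win_i = d > 0
                votes[win_i, i] += 1
                votes[~win_i, j] += 1
                margins[:, i] += d
                margins[:, j] -= d
                pair += 1
        out = np.empty(X.shape[0], dtype=self.classes_.dtype)
        for r in range(X.shape[0]):
            best = np.nonzero(votes[r] == votes[r].max())[0]
            if len(best) > 1:
                best = best[np.argsort(-margins[r, best], kind="stable")[:1]]
            out[r] = self.classes_[best[0]]
        return out


def model_to_dict(model: QualityModel) -> dict:
    """Serialize a trained model (subset, scaler, linear weights) to JSON."""
    clf = model.clf
    d = {
        "feature_set": list(model.feature_set),
        "scaler": {"mean": model.scaler.mean.tolist(),
                   "scale": model.scaler.scale.tolist()},
        "config": {"C": model.config.C, "max_iter": model.config.max_iter},
    }
    if isinstance(clf, _ConstantModel):
        d["constant_label"] = int(clf.label)
    else:
        d["classes"] = np.asarray(clf.classes_).tolist()
        d["coef"] = np.asarray(clf.coef_).tolist()
        d["intercept"] = np.asarray(clf.intercept_).tolist()
    return d


def model_from_dict(d: dict) -> QualityModel:
    """Rebuild a model saved by :func:`model_to_dict`."""
    scaler = Scaler(
        mean=np.asarray(d["scaler"]["mean"], dtype=float),
        scale=np.asarray(d["scaler"]["scale"], dtype=float),
    )
    config = SVMConfig(C=d["config"]["C"], max_iter=int(d["config"]["max_iter"]))
    if "constant_label" in d:
        clf: object = _ConstantModel(d["constant_label"])
    else:
        clf = _LinearOvO(np.asarray(d["classes"]),
                         np.asarray(d["coef"], dtype=float),
                         np.asarray(d["intercept"], dtype=float))
    return QualityModel(tuple(d["feature_set"]), scaler, clf, config)


def cross_dataset_eval(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    wrapper_result: WrapperResult,
    config: SVMConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Train on one full dataset with the subsets selected by its wrapper
    result and score on an untouched second dataset.

    Per size: best-subset accuracy across datasets, mean accuracy of the
    top10 members, and the accuracy of their majority-vote ensemble.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError("train and test feature schemas differ")
    rows = []
    for size in sorted(wrapper_result.results):
        best = wrapper_result.best(size)
        top = wrapper_result.top10(size)
        best_model = train_svm(X_train, y_train, config, feature_set=best.feature_set)
        best_across = float(np.mean(best_model.predict(X_test) == y_test))
        members = [train_svm(X_train, y_train, config, feature_set=r.feature_set)
                   for r in top]
        member_acc = [float(np.mean(mod.predict(X_test) == y_test))
                      for mod in members]
        voting = float(np.mean(vote_predict(members, X_test) == y_test))
        rows.append({
            "size": size,
            "best_within": best.mean,
            "best_across": best_across,
            "top10_across_mean": float(np.mean(member_acc)),
            "top10_voting": voting,
        })
    return pd.DataFrame(rows).set_index("size")
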