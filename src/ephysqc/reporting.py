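"""Descriptive statistics of feature tables and classifier outputs:
per-class histograms, KS tests with Bonferroni correction, PCA, chance
levels, feature-use statistics and agreement tables."""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .quality_model import WrapperResult, prediction_correlation

__all__ = [
    "feature_histograms",
    "ks_bonferroni",
    "pca_projection",
    "chance_levels",
    "feature_use_statistics",
    "agreement_table",
]


def feature_histograms(
    features: pd.DataFrame, labels: Sequence[str], bins: int = 20
) -> dict[str, dict]:
    """Per-feature, per-class histograms over the pooled [P5, P95] range.

    Values outside the pooled 5th-95th percentile range are excluded
    (extreme outliers); counts are normalised within each class so each
    histogram sums to 1.
    """
    labels = np.asarray(labels)
    out: dict[str, dict] = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        lo, hi = np.percentile(x, [5, 95])
        edges = np.linspace(lo, hi, bins + 1)
        per_class = {}
        for cls in np.unique(labels):
            vals = x[labels == cls]
            vals = vals[(vals >= lo) & (vals <= hi)]
            counts, _ = np.histogram(vals, bins=edges)
            total = counts.sum()
            per_class[str(cls)] = counts / total if total else counts.astype(float)
        out[col] = {"edges": edges, "counts": per_class}
    return out


def ks_bonferroni(
    features: pd.DataFrame,
    labels: Sequence[str],
    alphas: tuple[float, ...] = (0.05, 0.01),
) -> pd.DataFrame:
    """Two-sample KS tests for every feature and class pair.

    The Bonferroni family is all performed tests (16 features x 3 pairs =
    48 for the standard 3-class table); significance flags are reported at
    each corrected alpha. Class pairs with fewer than 2 observations on a
    side are skipped and listed with NaN p-values.
    """
    labels = np.asarray(labels)
    classes = sorted(np.unique(labels))
    pairs = list(combinations(classes, 2))
    n_tests = len(features.columns) * len(pairs)
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        for a, b in pairs:
            xa, xb = x[labels == a], x[labels == b]
            if len(xa) < 2 or len(xb) < 2:
                stat, p = float("nan"), float("nan")
            else:
                stat, p = stats.ks_2samp(xa, xb)
            row = {"feature": col, "class_a": a, "class_b": b,
                   "statistic": float(stat), "p_value": float(p),
                   "n_tests": n_tests}
            for alpha in alphas:
                key = f"significant_{alpha}"
                row[key] = bool(p < alpha / n_tests) if np.isfinite(p) else False
            rows.append(row)
    return pd.DataFrame(rows)


def pca_projection(features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Project recordings onto the first two principal components.

    Features are standardised (PCA of the correlation matrix) because the
    16 features carry incommensurate units. Returns (scores n x 2,
    variance fractions of the two leading components).
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 recordings")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    cov = Z.T @ Z / Z.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = evals.sum()
    fractions = evals[:2] / total if total > 0 else np.zeros(2)
    scores = Z @ evecs[:, :2]
    return scores, fractions


def chance_levels(labels: Sequence) -> dict[str, float]:
    """Guessing baselines from the class composition of a label vector.

    random = 1/k for k observed classes, proportional = sum p_i^2,
    majority = max p_i; all returned as fractions in [0, 1].
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label vector")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return {
        "random": 1.0 / len(p),
        "proportional": float(np.sum(p**2)),
        "majority": float(np.max(p)),
    }


def chance_levels_percent(labels: Sequence) -> dict[str, float]:
    """Chance levels as percentages, rounded the way they are usually
    printed: proportional to 1 decimal, random/majority to integers."""
    raw = chance_levels(labels)
    return {
        "random": round(100 * raw["random"], 1),
        "proportional": round(100 * raw["proportional"], 1),
        "majority": round(100 * raw["majority"]),
    }


def feature_use_statistics(wrapper_result: WrapperResult) -> pd.DataFrame:
    """How often each feature appears in the top10 group of each size."""
    n_features = wrapper_result.n_features
    rows = {}
    for size in sorted(wrapper_result.results):
        counts = np.zeros(n_features, dtype=int)
        for res in wrapper_result.top10(size):
            for f in res.feature_set:
                counts[f] += 1
        rows[size] = counts
    df = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"feature_{i}" for i in range(n_features)]
    )
    df.index.name = "size"
    return df


def agreement_table(predictions: Mapping[str, Sequence[int]]) -> pd.DataFrame:
    """Pairwise Pearson correlations of aligned -1/0/+1 prediction vectors
    from two or more sources; diagonal 1."""
    names = list(predictions)
    if len(names) < 2:
        raise ValueError("need at least 2 prediction sources")
    n = len(names)
    mat = np.eye(n)
    for i, j in combinations(range(n), 2):
        r = prediction_correlation(
            np.asarray(predictions[names[i]]), np.asarray(predictions[names[j]])
        )
        mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=names, columns=names)
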