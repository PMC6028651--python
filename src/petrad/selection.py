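"""AUC-based univariate feature ranking and cross-fold consensus.

Each feature is scored by the area under the ROC curve of its values
against the binary local-control label, computed with the rank (Mann-
Whitney) estimator so ties count one half. By default ranking uses the
oriented AUC ``max(AUC, 1 - AUC)``, so features whose low values predict
failure compete on equal footing with those whose high values do; the raw
direction is recorded. The per-fold top-k lists from cross-validation are
summarized into a consensus list ordered by selection frequency.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

__all__ = ["AUCRanking", "roc_auc", "rank_features", "consensus_features", "ranking_report"]


def roc_auc(scores, labels) -> float:
    """AUC as the probability a positive outscores a negative (ties = 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _auc_all_columns(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Raw AUC of every column at once via column-wise midranks."""
    pos = y == 1
    n1 = int(pos.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(X, axis=0)
    return (ranks[pos].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


@dataclasses.dataclass(frozen=True)
class AUCRanking:
    """Top-k features by (oriented) AUC with per-feature scores."""

    features: list[str]  # length k, descending AUC
    auc: dict[str, float]  # oriented AUC per ranked feature
    raw_auc: dict[str, float]  # unoriented AUC per ranked feature
    k: int


def rank_features(matrix: pd.DataFrame, labels, k: int, oriented: bool = True) -> AUCRanking:
    """Select the top-k columns of a feature matrix by AUC for the label.

    Ties in AUC break lexicographically by feature name; the result is
    deterministic and independent of row order.
    """
    if not 1 <= k <= matrix.shape[1]:
        raise ValueError(f"k={k} out of range for {matrix.shape[1]} features")
    y = np.asarray(labels)
    raw = _auc_all_columns(matrix.to_numpy(dtype=np.float64), y)
    score = np.maximum(raw, 1.0 - raw) if oriented else raw
    order = sorted(range(len(score)), key=lambda idx: (-score[idx], matrix.columns[idx]))
    top = order[:k]
    names = [str(matrix.columns[idx]) for idx in top]
    return AUCRanking(
        features=names,
        auc={n: float(score[idx]) for n, idx in zip(names, top)},
        raw_auc={n: float(raw[idx]) for n, idx in zip(names, top)},
        k=k,
    )


def consensus_features(per_fold_lists, k: int) -> list[str]:
    """Features most frequently selected across CV folds, truncated to k.

    Accepts plain name lists or :class:`AUCRanking` objects per fold. Order:
    selection frequency (desc), then mean per-fold AUC where available
    (desc), then name.
    """
    if len(per_fold_lists) == 0:
        raise ValueError("need at least one fold list")
    counts: dict[str, int] = {}
    auc_sums: dict[str, float] = {}
    for fold in per_fold_lists:
        if isinstance(fold, AUCRanking):
            names, aucs = fold.features, fold.auc
        else:
            names, aucs = list(fold), {}
        for name in names:
            counts[name] = counts.get(name, 0) + 1
            auc_sums[name] = auc_sums.get(name, 0.0) + aucs.get(name, 0.0)
    ordered = sorted(
        counts,
        key=lambda n: (-counts[n], -auc_sums[n] / counts[n], n),
    )
    return ordered[: min(k, len(ordered))]


def ranking_report(matrix: pd.DataFrame, labels, features: list[str]) -> pd.DataFrame:
    """Per-feature AUC and Mann-Whitney p-value table for a feature list."""
    y = np.asarray(labels)
    rows = []
    for name in features:
        x = matrix[name].to_numpy(dtype=np.float64)
        auc = roc_auc(x, y)
        try:
            p = float(mannwhitneyu(x[y == 1], x[y == 0]).pvalue)
        except ValueError:  # identical values in both groups
            p = 1.0
        rows.append({"feature": name, "auc": max(auc, 1 - auc), "raw_auc": auc, "p_value": p})
    return pd.DataFrame(rows)
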