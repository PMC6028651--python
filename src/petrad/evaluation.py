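"""Leave-one-out cross-validation with per-fold feature selection.

Each fold holds out one patient; feature ranking, hyperparameter search and
model fitting all see only the remaining patients, so the held-out row can
never influence its own fold's selected features or model. The per-fold
top-k lists are summarized into a consensus list for reporting only — it is
never fed back into the per-fold models. For the "all" feature group the 8
clinical covariates bypass the AUC screen and are always appended to the
selected radiomic features.
"""

from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np
import pandas as pd

from .models import ModelSpec, RiskPrediction, TrainedModel, predict_risk_batch, train_model
from .selection import AUCRanking, consensus_features, rank_features

__all__ = [
    "CLINICAL_COLUMNS",
    "FEATURE_GROUPS",
    "FoldResult",
    "CVResult",
    "ClassificationMetrics",
    "loocv",
    "classification_metrics",
    "assign_risk_groups",
]

CLINICAL_COLUMNS = [
    "location",
    "t_stage",
    "n_stage",
    "m_stage",
    "bed_gy",
    "chemo_cycles",
    "age",
    "gender",
]

FEATURE_GROUPS = ("clinical", "pre", "mid", "all_radiomic", "all")


class ClassificationMetrics(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float


@dataclasses.dataclass
class FoldResult:
    """One LOOCV fold: held-out patient, fold-local selection and model."""

    test_index: int
    test_id: str
    selected: list[str]
    ranking: AUCRanking | None
    params: dict
    prediction: RiskPrediction
    model: TrainedModel


@dataclasses.dataclass
class CVResult:
    """Aggregate LOOCV output: folds, confusion counts and consensus list."""

    folds: list[FoldResult]
    labels: np.ndarray
    confusion: dict[str, int]  # TP, FP, TN, FN
    metrics: ClassificationMetrics
    consensus: list[str]
    feature_group: str
    spec: ModelSpec
    k: int

    @property
    def risk_scores(self) -> np.ndarray:
        return np.array([f.prediction.risk_score for f in self.folds])

    @property
    def groups(self) -> list[str]:
        return [f.prediction.group for f in self.folds]


def _group_columns(columns, feature_group: str) -> tuple[list[str], list[str]]:
    """(radiomic columns subject to selection, clinical columns appended)."""
    pre = [c for c in columns if str(c).startswith("pre_")]
    mid = [c for c in columns if str(c).startswith("mid_")]
    clinical = [c for c in CLINICAL_COLUMNS if c in set(map(str, columns))]
    if feature_group == "clinical":
        if not clinical:
            raise ValueError("no clinical columns in the feature matrix")
        return [], clinical
    if feature_group == "pre":
        return pre, []
    if feature_group == "mid":
        return mid, []
    if feature_group == "all_radiomic":
        return pre + mid, []
    if feature_group == "all":
        return pre + mid, clinical
    raise ValueError(f"unknown feature group: {feature_group!r}")


def loocv(
    matrix: pd.DataFrame,
    labels,
    spec: ModelSpec,
    feature_group: str = "all",
    k: int = 25,
    patient_ids: list[str] | None = None,
) -> CVResult:
    """Leave-one-out CV with AUC top-k selection inside every fold.

    Parameters
    ----------
    matrix : patients x features, columns ``pre_*`` / ``mid_*`` plus the 8
        clinical covariates.
    labels : binary outcome, 1 = local progression.
    k : radiomic features selected per fold (ignored for the clinical group).
    """
    y = np.asarray(labels, dtype=int)
    n = len(y)
    if n < 4:
        raise ValueError("leave-one-out CV needs at least 4 patients")
    if matrix.shape[0] != n:
        raise ValueError("matrix rows and labels length differ")
    ids = patient_ids if patient_ids is not None else [str(i) for i in matrix.index]
    radiomic_cols, clinical_cols = _group_columns(matrix.columns, feature_group)
    select = len(radiomic_cols) > 0

    folds: list[FoldResult] = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        y_tr = y[train]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(
                f"training fold {i} lost a class; the cohort is too small or "
                "too imbalanced for leave-one-out CV"
            )
        if select:
            ranking = rank_features(
                matrix.loc[train, radiomic_cols], y_tr, min(k, len(radiomic_cols))
            )
            cols = ranking.features + clinical_cols
        else:
            ranking = None
            cols = list(clinical_cols)
        model = train_model(spec, matrix.loc[train, cols], y_tr)
        pred = predict_risk_batch(model, matrix.loc[[matrix.index[i]], cols])[0]
        folds.append(
            FoldResult(
                test_index=i,
                test_id=ids[i],
                selected=ranking.features if ranking else [],
                ranking=ranking,
                params=model.params,
                prediction=pred,
                model=model,
            )
        )

    groups = [f.prediction.group for f in folds]
    confusion = _confusion(groups, y)
    metrics = classification_metrics(groups, y)
    consensus = (
        consensus_features([f.ranking for f in folds], min(k, len(radiomic_cols)))
        if select
        else []
    )
    return CVResult(folds, y, confusion, metrics, consensus, feature_group, spec, k)


def _as_binary_predictions(predictions) -> np.ndarray:
    preds = np.asarray(predictions)
    if preds.dtype.kind in "UO":
        return np.array([1 if p == "high" else 0 for p in preds])
    return preds.astype(int)


def _confusion(predictions, labels) -> dict[str, int]:
    pred = _as_binary_predictions(predictions)
    y = np.asarray(labels, dtype=int)
    return {
        "TP": int(((pred == 1) & (y == 1)).sum()),
        "FP": int(((pred == 1) & (y == 0)).sum()),
        "TN": int(((pred == 0) & (y == 0)).sum()),
        "FN": int(((pred == 0) & (y == 1)).sum()),
    }


def classification_metrics(predictions, labels) -> ClassificationMetrics:
    """Accuracy, sensitivity (label-1 recall) and specificity.

    ``predictions`` may be "high"/"low" group calls or binary values.
    """
    y = np.asarray(labels, dtype=int)
    if len(y) == 0:
        raise ValueError("empty input")
    pred = _as_binary_predictions(predictions)
    if len(pred) != len(y):
        raise ValueError("predictions and labels length differ")
    c = _confusion(pred, y)
    if c["TP"] + c["FN"] == 0:
        raise ValueError("no positive labels: sensitivity undefined")
    if c["TN"] + c["FP"] == 0:
        raise ValueError("no negative labels: specificity undefined")
    return ClassificationMetrics(
        accuracy=(c["TP"] + c["TN"]) / len(y),
        sensitivity=c["TP"] / (c["TP"] + c["FN"]),
        specificity=c["TN"] / (c["TN"] + c["FP"]),
    )


def assign_risk_groups(scores, rule: str = "median_split") -> list[str]:
    """Split patients into high/low risk groups by score.

    ``threshold_0.5``: high iff score > 0.5. ``median_split``: high iff
    score > the cohort median. Both resulting groups must be non-empty
    (required for the downstream survival comparison).
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(scores) < 2:
        raise ValueError("need at least 2 patients to form risk groups")
    if rule == "threshold_0.5":
        cut = 0.5
    elif rule == "median_split":
        cut = float(np.median(scores))
    else:
        raise ValueError(f"unknown risk-group rule: {rule!r}")
    high = scores > cut
    if high.all() or not high.any():
        raise ValueError(
            f"degenerate risk distribution: rule {rule!r} with cut {cut:g} "
            f"puts all {len(scores)} patients in one group"
        )
    return ["high" if h else "low" for h in high]
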