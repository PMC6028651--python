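"""Risk-score models: random forest, SVM-RBF, logistic regression, ELM.

Each family is trained with a grid search over its published hyperparameter
ranges and emits a per-patient risk score of local failure plus a high/low
risk-group call under the family's decision rule:

* forest — score = fraction of the 100 trees voting for failure; high risk
  iff score > 0.5. Each tree is grown on p samples drawn with replacement
  (p in 5..20) with q candidate features per node (q in 5..50); the grid is
  selected by out-of-bag accuracy.
* svm — RBF kernel, C = 10^t (t in -5..5), sigma in 0.1..1.0; the signed
  distance to the hyperplane (positive toward local control) is the output;
  high risk iff the distance is <= 0.
* lr — ridge-regularized logistic regression; score = predicted failure
  probability; high risk iff score > 0.5 (strict).
* elm — single-hidden-layer network with random hidden weights (5..30
  nodes, sigmoid or sine activation) and least-squares output weights over
  two output nodes (control, failure); high risk iff the failure node's
  output is at least the control node's.

svm/lr/elm grids use 5-fold stratified inner resampling on the training
fold, scored by accuracy; features are standardized with training-fold
mean/SD for the scale-sensitive families (svm, lr, elm) and used raw for
the forest. Everything is deterministic given the spec seed.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "RiskPrediction",
    "default_grid",
    "train_model",
    "predict_risk",
    "predict_risk_batch",
]

FAMILIES = ("rf", "svm", "lr", "elm")


def default_grid(family: str) -> list[dict[str, Any]]:
    """The published hyperparameter grid of one model family."""
    if family == "rf":
        return [
            {"p": p, "q": q}
            for p in range(5, 25, 5)
            for q in range(5, 55, 5)
        ]
    if family == "svm":
        return [
            {"C": 10.0**t, "sigma": round(0.1 * s, 10)}
            for t in range(-5, 6)
            for s in range(1, 11)
        ]
    if family == "lr":
        return [{}]
    if family == "elm":
        return [
            {"hidden": h, "activation": act}
            for h in range(5, 35, 5)
            for act in ("sigmoid", "sine")
        ]
    raise ValueError(f"unknown model family: {family!r}")


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Model family, hyperparameter grid and seed."""

    family: str
    grid: tuple = None  # type: ignore[assignment]
    n_trees: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family: {self.family!r}")
        grid = self.grid
        if grid is None:
            grid = default_grid(self.family)
        grid = tuple(dict(g) for g in grid)
        if len(grid) == 0:
            raise ValueError("hyperparameter grid must be non-empty")
        object.__setattr__(self, "grid", grid)


@dataclasses.dataclass(frozen=True)
class RiskPrediction:
    """Per-patient risk score and risk-group call."""

    risk_score: float
    group: str  # "high" | "low"
    rule: str


@dataclasses.dataclass
class TrainedModel:
    """Immutable fit result: family, chosen grid point and fitted state."""

    family: str
    params: dict[str, Any]
    feature_names: list[str]
    seed: int
    _state: Any = dataclasses.field(repr=False, default=None)
    _scaler: tuple[np.ndarray, np.ndarray] | None = dataclasses.field(repr=False, default=None)


# ---------------------------------------------------------------- forest

class _Forest:
    """Bagged decision trees: p bootstrap samples/tree, q features/node."""

    def __init__(self, p: int, q: int, n_trees: int, seed: int):
        self.p, self.q, self.n_trees, self.seed = p, q, n_trees, seed

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Forest":
        rng = np.random.default_rng(self.seed)
        n, d = X.shape
        p = min(self.p, n)
        self.bootstrap_ = rng.integers(0, n, size=(self.n_trees, p))
        tree_seeds = rng.integers(0, 2**31, size=self.n_trees)
        self.trees_ = []
        for t in range(self.n_trees):
            idx = self.bootstrap_[t]
            tree = DecisionTreeClassifier(
                max_features=min(self.q, d), random_state=int(tree_seeds[t])
            )
            tree.fit(X[idx], y[idx], check_input=False)
            self.trees_.append(tree)
        return self

    def _tree_votes(self, X: np.ndarray) -> np.ndarray:
        """(n_trees, n_samples) matrix of 0/1 failure votes."""
        X = np.ascontiguousarray(X, dtype=np.float32)
        return np.stack(
            [tree.predict(X, check_input=False) for tree in self.trees_]
        ).astype(np.float64)

    def vote_fraction(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting for local failure, per sample."""
        return self._tree_votes(X).mean(axis=0)

    def oob_accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        votes = self._tree_votes(X)
        n = len(y)
        in_bag = np.zeros((self.n_trees, n), dtype=bool)
        for t in range(self.n_trees):
            in_bag[t, self.bootstrap_[t]] = True
        oob = ~in_bag
        n_oob = oob.sum(axis=0)
        covered = n_oob > 0
        frac = np.zeros(n)
        frac[covered] = (votes * oob).sum(axis=0)[covered] / n_oob[covered]
        pred = (frac > 0.5).astype(int)
        return float((pred[covered] == y[covered]).mean())


# ---------------------------------------------------------------- elm

def _elm_activation(name: str):
    if name == "sigmoid":
        return lambda z: 1.0 / (1.0 + np.exp(-z))
    if name == "sine":
        return np.sin
    raise ValueError(f"unknown ELM activation: {name!r}")


class _ELM:
    """Random-hidden-layer network, least-squares output weights, 2 outputs.

    Hidden weights for h nodes are the first h rows of one fixed random
    matrix per seed, so training error is monotone in h for a fixed seed.
    """

    MAX_HIDDEN = 30

    def __init__(self, hidden: int, activation: str, seed: int):
        self.hidden, self.activation, self.seed = hidden, activation, seed

    def _hidden_layer(self, X: np.ndarray, d: int):
        rng = np.random.default_rng(self.seed)
        W = rng.normal(size=(self.MAX_HIDDEN, d))[: self.hidden]
        b = rng.uniform(-1.0, 1.0, size=self.MAX_HIDDEN)[: self.hidden]
        act = _elm_activation(self.activation)
        return act(X @ W.T + b)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_ELM":
        self.d_ = X.shape[1]
        H = self._hidden_layer(X, self.d_)
        T = np.column_stack([1.0 - y, y.astype(np.float64)])  # (control, failure)
        self.beta_, *_ = np.linalg.lstsq(H, T, rcond=None)
        return self

    def outputs(self, X: np.ndarray) -> np.ndarray:
        return self._hidden_layer(X, self.d_) @ self.beta_


# ---------------------------------------------------------------- training

def _as_array(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64), [str(c) for c in X.columns]
    X = np.asarray(X, dtype=np.float64)
    return X, [f"f{i}" for i in range(X.shape[1])]


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def _cv_accuracy(fit_predict, X, y, n_splits: int, seed: int) -> float:
    """Mean held-out accuracy of a fit/predict callable over stratified folds."""
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        pred = fit_predict(X[train_idx], y[train_idx], X[test_idx])
        accs.append(float((pred == y[test_idx]).mean()))
    return float(np.mean(accs))


def train_model(spec: ModelSpec, X, y) -> TrainedModel:
    """Grid-search and fit one model family on a training fold.

    The best grid point is chosen on the training data only (OOB accuracy
    for the forest, 5-fold stratified inner CV accuracy otherwise, ties
    broken by grid order); the returned model records the chosen point.
    """
    Xa, names = _as_array(X)
    y = np.asarray(y, dtype=int)
    if Xa.shape[0] != len(y):
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    single_class = len(classes) < 2
    if single_class and spec.family != "rf":
        raise ValueError(
            f"{spec.family} requires both classes in the training labels"
        )

    if spec.family == "rf":
        Xf = np.ascontiguousarray(Xa, dtype=np.float32)
        # p caps at the fold size and q at the feature count; clamped grid
        # points that coincide are evaluated once (first occurrence wins)
        n, d = Xf.shape
        grid, seen = [], set()
        for g in spec.grid:
            clamped = {"p": min(g["p"], n), "q": min(g["q"], d)}
            key = (clamped["p"], clamped["q"])
            if key not in seen:
                seen.add(key)
                grid.append(clamped)
        if single_class or len(grid) == 1:
            best = grid[0]
        else:
            scores = []
            for g in grid:
                forest = _Forest(g["p"], g["q"], spec.n_trees, spec.seed).fit(Xf, y)
                scores.append(forest.oob_accuracy(Xf, y))
            best = grid[int(np.argmax(scores))]
        state = _Forest(best["p"], best["q"], spec.n_trees, spec.seed).fit(Xf, y)
        return TrainedModel(spec.family, dict(best), names, spec.seed, state, None)

    mean, sd = _standardize_fit(Xa)
    Xs = (Xa - mean) / sd
    minority = int(np.bincount(y).min())
    n_splits = min(5, minority)

    if spec.family == "svm":
        def make(g):
            return SVC(C=g["C"], kernel="rbf", gamma=1.0 / (2.0 * g["sigma"] ** 2))
    elif spec.family == "lr":
        def make(g):
            return LogisticRegression(max_iter=5000)
    else:  # elm
        def make(g):
            return _ELM(g["hidden"], g["activation"], spec.seed)

    if len(spec.grid) == 1 or n_splits < 2:
        best = spec.grid[0]
    else:
        scores = []
        for g in spec.grid:
            if spec.family == "elm":
                def fp(Xt, yt, Xv, g=g):
                    m = make(g).fit(Xt, yt)
                    out = m.outputs(Xv)
                    return (out[:, 1] >= out[:, 0]).astype(int)
            else:
                def fp(Xt, yt, Xv, g=g):
                    return make(g).fit(Xt, yt).predict(Xv)
            scores.append(_cv_accuracy(fp, Xs, y, n_splits, spec.seed))
        best = spec.grid[int(np.argmax(scores))]

    state = make(best).fit(Xs, y)
    return TrainedModel(spec.family, dict(best), names, spec.seed, state, (mean, sd))


# ---------------------------------------------------------------- prediction

_RULES = {
    "rf": "high iff tree-vote fraction > 0.5",
    "lr": "high iff failure probability > 0.5",
    "svm": "high iff signed distance to control <= 0",
    "elm": "high iff failure output node >= control output node",
}


def predict_risk_batch(model: TrainedModel, X) -> list[RiskPrediction]:
    """Risk score and group for each row of a feature matrix."""
    Xa, names = _as_array(X)
    if isinstance(X, pd.DataFrame) and names != model.feature_names:
        raise ValueError("feature names do not match the training matrix")
    if Xa.shape[1] != len(model.feature_names):
        raise ValueError(
            f"expected {len(model.feature_names)} features, got {Xa.shape[1]}"
        )
    if model._scaler is not None:
        mean, sd = model._scaler
        Xa = (Xa - mean) / sd

    if model.family == "rf":
        scores = model._state.vote_fraction(Xa)
        high = scores > 0.5
    elif model.family == "lr":
        scores = model._state.predict_proba(Xa)[:, 1]
        high = scores > 0.5
    elif model.family == "svm":
        # decision_function is positive toward the failure class; the
        # published signed distance is positive toward control
        df = model._state.decision_function(Xa)
        scores = df
        high = -df <= 0
    else:  # elm
        out = model._state.outputs(Xa)
        scores = out[:, 1] - out[:, 0]
        high = scores >= 0

    rule = _RULES[model.family]
    return [
        RiskPrediction(float(s), "high" if h else "low", rule)
        for s, h in zip(scores, high)
    ]


def predict_risk(model: TrainedModel, x) -> RiskPrediction:
    """Risk score and group for a single feature row."""
    if isinstance(x, pd.Series):
        x = x.to_frame().T
    else:
        x = np.asarray(x, dtype=np.float64).reshape(1, -1)
    return predict_risk_batch(model, x)[0]
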