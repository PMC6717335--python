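"""Tree-ensemble pathways: balanced/plain forests with per-tree confidence,
hyperparameter-tuned forests with response-outlier flagging, and the
error model used for uncertainty-based applicability domains.

The balanced random forest grows each tree on a *balanced bootstrap*: every
class contributes exactly ``n_min`` indices drawn with replacement, where
``n_min`` is the minority-class size.  This undersamples majority classes
per tree while the ensemble as a whole still sees all the data, which is
the standard remedy for the strong class imbalance of toxicity endpoints.

Prediction confidence is the fraction of trees agreeing with the majority
vote (classification) or the tree-wise standard deviation (regression); both
feed the confidence and error-model AD constructions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    ExtraTreesRegressor,
    IsolationForest,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "balanced_bootstrap",
    "ForestClassifier",
    "ForestRegressor",
    "fit_forest",
    "predict_with_confidence",
    "HptGrid",
    "hpt_select",
    "flag_response_outliers",
    "fit_error_model",
    "error_model_features",
]


def balanced_bootstrap(labels, rng) -> np.ndarray:
    """Index sample with equal class counts: n_min draws with replacement per class."""
    labels = np.asarray(labels)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 non-empty classes")
    n_min = int(counts.min())
    parts = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        parts.append(rng.choice(idx, size=n_min, replace=True))
    return np.concatenate(parts)


class ForestClassifier:
    """Random forest with per-tree vote access and optional balanced sampling.

    ``sampling='balanced'`` grows each tree on a balanced bootstrap (BRF);
    ``'plain'`` uses an ordinary bootstrap of n rows.  Trees are sklearn
    decision trees with sqrt feature subsampling.  Seed-deterministic.
    """

    def __init__(self, n_trees: int = 100, sampling: str = "balanced", seed: int = 0,
                 max_features: str | int | float = "sqrt") -> None:
        if sampling not in ("plain", "balanced"):
            raise ValueError("sampling must be 'plain' or 'balanced'")
        self.n_trees = n_trees
        self.sampling = sampling
        self.seed = seed
        self.max_features = max_features

    def get_params(self, deep: bool = True) -> dict:
        return {"n_trees": self.n_trees, "sampling": self.sampling, "seed": self.seed,
                "max_features": self.max_features}

    def set_params(self, **params) -> "ForestClassifier":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "ForestClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D and align with y")
        rng = np.random.default_rng(self.seed)
        self.classes_ = np.unique(y)
        self.trees_ = []
        n = X.shape[0]
        for t in range(self.n_trees):
            if self.sampling == "balanced":
                idx = balanced_bootstrap(y, rng)
            else:
                idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
        return self

    def _votes(self, X) -> np.ndarray:
        """(n_trees, n_samples) array of per-tree predicted labels."""
        X = np.asarray(X, dtype=float)
        return np.stack([t.predict(X) for t in self.trees_])

    def predict(self, X) -> np.ndarray:
        return self.predict_with_confidence(X)[0]

    def predict_with_confidence(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Majority label and the agreeing-tree fraction per sample."""
        votes = self._votes(X)
        n_samples = votes.shape[1]
        labels = np.empty(n_samples, dtype=self.classes_.dtype)
        conf = np.empty(n_samples, dtype=float)
        for j in range(n_samples):
            vals, counts = np.unique(votes[:, j], return_counts=True)
            i = int(np.argmax(counts))  # ties: first label in sorted order
            labels[j] = vals[i]
            conf[j] = counts[i] / votes.shape[0]
        return labels, conf


class ForestRegressor:
    """Regression forest with tree-wise spread as an auxiliary confidence signal."""

    def __init__(self, n_trees: int = 100, seed: int = 0,
                 max_features: str | int | float = 1.0) -> None:
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features

    def get_params(self, deep: bool = True) -> dict:
        return {"n_trees": self.n_trees, "seed": self.seed, "max_features": self.max_features}

    def set_params(self, **params) -> "ForestRegressor":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "ForestRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.model_ = RandomForestRegressor(
            n_estimators=self.n_trees, random_state=self.seed,
            max_features=self.max_features,
        ).fit(X, y)
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(np.asarray(X, dtype=float))

    def predict_with_confidence(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Mean of tree outputs and the per-sample tree standard deviation."""
        X = np.asarray(X, dtype=float)
        per_tree = np.stack([t.predict(X) for t in self.model_.estimators_])
        return per_tree.mean(axis=0), per_tree.std(axis=0)

    def tree_predictions(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.stack([t.predict(X) for t in self.model_.estimators_])


def fit_forest(X, y, task: str = "classification", n_trees: int = 100, seed: int = 0,
               sampling: str = "plain"):
    """Fit a forest of the requested task; BRF via ``sampling='balanced'``."""
    if task == "classification":
        return ForestClassifier(n_trees=n_trees, sampling=sampling, seed=seed).fit(X, y)
    if task == "regression":
        return ForestRegressor(n_trees=n_trees, seed=seed).fit(X, y)
    raise ValueError("task must be 'classification' or 'regression'")


def predict_with_confidence(model, X) -> tuple[np.ndarray, np.ndarray]:
    """Dispatch to the model's confidence-aware prediction."""
    return model.predict_with_confidence(X)


@dataclass(frozen=True)
class HptGrid:
    """Hyperparameter grid for the tuned-forest pathway.

    ``splitrule`` options are 'gini'/'extratrees' for classification and
    'variance'/'extratrees' for regression; 500 trees by default.
    """

    mtry: tuple[int, ...] = (2, 8, 32)
    splitrule: tuple[str, ...] = ("gini", "extratrees")
    min_node_size: tuple[int, ...] = (1, 5)
    n_trees: int = 500

    def points(self):
        for m in self.mtry:
            for s in self.splitrule:
                for ns in self.min_node_size:
                    yield {"mtry": m, "splitrule": s, "min_node_size": ns}


def _make_forest(task: str, point: dict, n_trees: int, seed: int):
    kwargs = dict(
        n_estimators=n_trees,
        max_features=point["mtry"],
        min_samples_leaf=point["min_node_size"],
        random_state=seed,
    )
    if point["splitrule"] == "extratrees":
        cls = ExtraTreesClassifier if task == "classification" else ExtraTreesRegressor
        kwargs["bootstrap"] = True
    else:
        cls = RandomForestClassifier if task == "classification" else RandomForestRegressor
    return cls(**kwargs)


def _bootstrap_score(task, model_factory, X, y, n_boot, rng) -> float:
    """Out-of-bag performance over bootstrap refits.

    Regression: negative RMSE; classification: balanced accuracy — higher is
    better for both.
    """
    n = X.shape[0]
    scores = []
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        model = model_factory(int(rng.integers(0, 2**31 - 1)))
        model.fit(X[idx], y[idx])
        pred = model.predict(X[oob])
        if task == "regression":
            scores.append(-float(np.sqrt(np.mean((pred - y[oob]) ** 2))))
        else:
            from .metrics import balanced_accuracy

            scores.append(balanced_accuracy(y[oob], pred))
    return float(np.mean(scores)) if scores else -np.inf


def hpt_select(X, y, grid: HptGrid, task: str = "classification", n_boot: int = 10,
               seed: int = 0, eval_trees: int | None = None):
    """Grid search by bootstrap internal validation; refit the winner on all data.

    ``eval_trees`` can shrink the forests used during scoring; the final
    refit always uses ``grid.n_trees``.  Ties break by grid order.
    Returns (fitted model, chosen point, per-point scores).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    points = list(grid.points())
    if not points:
        raise ValueError("empty hyperparameter grid")
    n_eval = eval_trees or grid.n_trees
    rng = np.random.default_rng(seed)
    scores = []
    for point in points:
        p = {**point, "mtry": min(point["mtry"], X.shape[1])}
        score = _bootstrap_score(
            task, lambda s, p=p: _make_forest(task, p, n_eval, s), X, y, n_boot, rng
        )
        scores.append(score)
    best = int(np.argmax(scores))  # argmax keeps the first (grid-order) maximum
    chosen = {**points[best], "mtry": min(points[best]["mtry"], X.shape[1])}
    model = _make_forest(task, chosen, grid.n_trees, seed).fit(X, y)
    return model, points[best], scores


def flag_response_outliers(
    X, y, task: str = "regression", n_boot: int = 100, n_trees: int = 50, seed: int = 0,
    q_iso: float = 0.99, q_err: float = 0.95, q_var: float = 0.95,
) -> np.ndarray:
    """Flag anomalous training compounds before the tuned-forest refit.

    A compound is flagged when its isolation-forest anomaly score exceeds the
    ``q_iso`` quantile, or when both its out-of-bag absolute error and its
    prediction variance across ``n_boot`` bootstrap refits exceed the
    ``q_err`` / ``q_var`` quantiles.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    iso = IsolationForest(random_state=seed).fit(X)
    iso_score = -iso.score_samples(X)  # higher = more anomalous
    preds: list[list[float]] = [[] for _ in range(n)]
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            continue
        if task == "regression":
            model = RandomForestRegressor(
                n_estimators=n_trees, random_state=int(rng.integers(0, 2**31 - 1))
            )
        else:
            model = RandomForestClassifier(
                n_estimators=n_trees, random_state=int(rng.integers(0, 2**31 - 1))
            )
        model.fit(X[idx], y[idx])
        for i, p in zip(oob, model.predict(X[oob])):
            preds[i].append(float(p) if task == "regression" else p)
    if task == "regression":
        err = np.array([abs(np.mean(p) - y[i]) if p else 0.0 for i, p in enumerate(preds)])
        var = np.array([np.var(p) if len(p) > 1 else 0.0 for p in preds])
    else:
        err = np.array([np.mean([pi != y[i] for pi in p]) if p else 0.0
                        for i, p in enumerate(preds)])
        var = err * (1 - err)  # vote dispersion
    flags = iso_score > np.quantile(iso_score, q_iso)
    if err.max() > 0:
        flags = flags | ((err >= np.quantile(err, q_err)) & (var >= np.quantile(var, q_var)))
    return flags


def error_model_features(
    query_X, train_X, model: ForestRegressor | None = None, k: int = 5
) -> np.ndarray:
    """AD-metric matrix for the error model.

    Per query row: mean and max similarity (1 / (1 + Manhattan distance)) to
    the k nearest training rows, plus — when a fitted regression forest is
    given — the tree-prediction SD.  These are the uncertainty covariates
    the error model regresses cross-validated absolute errors on.
    """
    from scipy.spatial.distance import cdist

    query_X = np.asarray(query_X, dtype=float)
    train_X = np.asarray(train_X, dtype=float)
    D = cdist(query_X, train_X, metric="cityblock")
    D_sorted = np.sort(D, axis=1)
    # a query row identical to a training row sees itself at distance 0; keep it
    near = D_sorted[:, :k]
    sim = 1.0 / (1.0 + near)
    feats = [sim.mean(axis=1), sim.max(axis=1)]
    if model is not None:
        feats.append(model.predict_with_confidence(query_X)[1])
    return np.column_stack(feats)


def fit_error_model(ad_metrics, cv_abs_errors, seed: int = 0, n_trees: int = 100):
    """Forest regressor mapping AD metrics to expected absolute error (>= 0)."""
    M = np.asarray(ad_metrics, dtype=float)
    e = np.asarray(cv_abs_errors, dtype=float)
    if (e < 0).any():
        raise ValueError("cross-validated absolute errors must be non-negative")
    if M.shape[0] != e.size:
        raise ValueError("metrics rows must align with the error vector")
    inner = RandomForestRegressor(n_estimators=n_trees, random_state=seed).fit(M, e)

    class _ErrorModel:
        def __init__(self, forest):
            self.forest_ = forest

        def predict(self, metrics) -> np.ndarray:
            return np.clip(self.forest_.predict(np.asarray(metrics, dtype=float)), 0.0, None)

    return _ErrorModel(inner)
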