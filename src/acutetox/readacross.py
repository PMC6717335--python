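"""Similarity-thresholded k-nearest-neighbor read-across with abstention.

The predictor refines plain kNN with decision rules that make it abstain
rather than extrapolate:

1. candidate neighbors must exceed a similarity threshold ``t_sim1``; the k
   most similar such training compounds are retained;
2. no candidate -> no prediction (``NO_NEIGHBOR``);
3. a single candidate predicts only if its similarity also exceeds a second,
   stricter threshold ``t_sim2`` (the prediction is then that neighbor's
   experimental value), otherwise ``SINGLE_BELOW_T2``;
4. with two or more candidates a prediction is returned only when the spread
   of their experimental values (max - min) is below ``t_minmax``
   (``RANGE_EXCEEDED`` otherwise); the prediction is the similarity-weighted
   mean with weights SI^enhancement, so larger enhancement factors pull the
   estimate toward the most similar neighbor.

Thresholds are strict in the direction the rules state: similarities must be
``>`` the thresholds and the value spread must be ``<`` ``t_minmax``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .similarity import IntegratedSimilarityWeights, compound_si

logger = logging.getLogger(__name__)

__all__ = [
    "IstKnnParams",
    "ReadAcrossResult",
    "ABSTAIN",
    "default_param_grid",
    "istknn_predict_from_sims",
    "IstKnnRegressor",
    "istknn_loo_cv",
    "istknn_grid_search",
]

ABSTAIN = "ABSTAIN"


@dataclass(frozen=True)
class IstKnnParams:
    """The five tunable read-across parameters.

    Grid ranges used for optimization: k in 2..5, t_sim1 in 0.70..0.90
    (step 0.05), t_sim2 in {0.85, 0.90}, enhancement in 1..3, t_minmax in
    1.0..2.0 (step 0.5).
    """

    k: int = 3
    t_sim1: float = 0.75
    t_sim2: float = 0.85
    enhancement: int = 1
    t_minmax: float = 1.5

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 <= self.t_sim1 <= 1 and 0 <= self.t_sim2 <= 1):
            raise ValueError("similarity thresholds must lie in [0, 1]")
        if self.t_sim2 < self.t_sim1:
            raise ValueError("t_sim2 must be >= t_sim1")
        if self.enhancement < 1:
            raise ValueError("enhancement must be >= 1")
        if self.t_minmax <= 0:
            raise ValueError("t_minmax must be positive")


def default_param_grid() -> list[IstKnnParams]:
    """The full optimization grid (k x t_sim1 x t_sim2 x enhancement x t_minmax)."""
    grid = []
    for k, t1, t2, e, tmm in itertools.product(
        range(2, 6),
        [round(0.70 + 0.05 * i, 2) for i in range(5)],
        (0.85, 0.90),
        (1, 2, 3),
        (1.0, 1.5, 2.0),
    ):
        if t2 >= t1:
            grid.append(IstKnnParams(k=k, t_sim1=t1, t_sim2=t2, enhancement=e, t_minmax=tmm))
    return grid


@dataclass(frozen=True)
class ReadAcrossResult:
    """Outcome of one read-across prediction (value or abstention + reason)."""

    prediction: float | None
    neighbors: tuple[tuple[str, float, float], ...]  # (id, SI, value)
    reason: str  # OK | NO_NEIGHBOR | SINGLE_BELOW_T2 | RANGE_EXCEEDED

    def __post_init__(self) -> None:
        if (self.prediction is not None) != (self.reason == "OK"):
            raise ValueError("prediction present iff reason == OK")

    @property
    def abstained(self) -> bool:
        return self.prediction is None


def istknn_predict_from_sims(
    sims, values, params: IstKnnParams, ids=None
) -> ReadAcrossResult:
    """Apply the read-across decision rules given precomputed SI values.

    ``sims`` and ``values`` align with the training compounds; ``ids`` default
    to positional indices.  SI ties during neighbor capping are broken stably
    by (SI descending, id ascending).
    """
    sims = np.asarray(sims, dtype=float)
    values = np.asarray(values, dtype=float)
    if sims.size == 0:
        raise ValueError("empty training set")
    if sims.shape != values.shape:
        raise ValueError("sims and values must align")
    if ids is None:
        ids = [str(i) for i in range(sims.size)]
    candidates = [(str(ids[i]), float(sims[i]), float(values[i]))
                  for i in range(sims.size) if sims[i] > params.t_sim1]
    candidates.sort(key=lambda t: (-t[1], t[0]))
    retained = tuple(candidates[: params.k])
    if len(retained) == 0:
        return ReadAcrossResult(None, (), "NO_NEIGHBOR")
    if len(retained) == 1:
        nid, si, val = retained[0]
        if si > params.t_sim2:
            return ReadAcrossResult(val, retained, "OK")
        return ReadAcrossResult(None, retained, "SINGLE_BELOW_T2")
    vals = [v for _, _, v in retained]
    if max(vals) - min(vals) >= params.t_minmax:
        return ReadAcrossResult(None, retained, "RANGE_EXCEEDED")
    w = np.array([si for _, si, _ in retained]) ** params.enhancement
    pred = float(np.dot(w, vals) / w.sum())
    return ReadAcrossResult(pred, retained, "OK")


class IstKnnRegressor:
    """Read-across regressor over the integrated similarity index.

    scikit-learn style: ``fit(smiles, y)`` stores the neighbor pool (training
    values are expected on the log mmol/kg scale), ``predict`` returns an
    array with ``nan`` at abstentions; ``predict_results`` exposes the full
    per-compound :class:`ReadAcrossResult`.  A custom pairwise similarity
    function (``sim_fn(a, b) -> SI``) replaces the structural SI when given,
    which also makes the class usable on precomputed similarity tables.
    """

    def __init__(
        self,
        k: int = 3,
        t_sim1: float = 0.75,
        t_sim2: float = 0.85,
        enhancement: int = 1,
        t_minmax: float = 1.5,
        sim_fn=None,
        si_weights: IntegratedSimilarityWeights | None = None,
    ) -> None:
        self.k = k
        self.t_sim1 = t_sim1
        self.t_sim2 = t_sim2
        self.enhancement = enhancement
        self.t_minmax = t_minmax
        self.sim_fn = sim_fn
        self.si_weights = si_weights

    # minimal get/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "k": self.k, "t_sim1": self.t_sim1, "t_sim2": self.t_sim2,
            "enhancement": self.enhancement, "t_minmax": self.t_minmax,
            "sim_fn": self.sim_fn, "si_weights": self.si_weights,
        }

    def set_params(self, **params) -> "IstKnnRegressor":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    @property
    def params_(self) -> IstKnnParams:
        return IstKnnParams(self.k, self.t_sim1, self.t_sim2, self.enhancement, self.t_minmax)

    def _sim(self, a, b) -> float:
        if self.sim_fn is not None:
            return float(self.sim_fn(a, b))
        w = self.si_weights or IntegratedSimilarityWeights()
        return compound_si(a, b, weights=w)

    def fit(self, X, y, ids=None) -> "IstKnnRegressor":
        X = list(X)
        y = np.asarray(y, dtype=float)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(X) != y.size:
            raise ValueError("X and y must align")
        self.train_X_ = X
        self.train_y_ = y
        self.train_ids_ = [str(i) for i in range(len(X))] if ids is None else [str(i) for i in ids]
        return self

    def predict_results(self, X) -> list[ReadAcrossResult]:
        self._check_fitted()
        out = []
        for target in X:
            sims = np.array([self._sim(target, t) for t in self.train_X_])
            out.append(istknn_predict_from_sims(sims, self.train_y_, self.params_, self.train_ids_))
        return out

    def predict(self, X) -> np.ndarray:
        return np.array(
            [r.prediction if r.prediction is not None else np.nan for r in self.predict_results(X)]
        )

    def _check_fitted(self) -> None:
        if not hasattr(self, "train_X_"):
            raise RuntimeError("IstKnnRegressor is not fitted")


def _regression_summary(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float, float]:
    resid = pred - truth
    mae = float(np.mean(np.abs(resid)))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = float("nan") if ss_tot == 0 else 1.0 - float(np.sum(resid ** 2)) / ss_tot
    return r2, mae, rmse


def istknn_loo_cv(
    sim_matrix, values, params: IstKnnParams, ids=None
) -> dict:
    """Leave-one-out cross-validation on a precomputed similarity matrix.

    Each compound is predicted from the pool with itself excluded.  Returns
    ``{"r2", "mae", "rmse", "coverage"}``; metrics are computed over the
    predicted subset only and are ``nan`` when coverage is zero.
    """
    S = np.asarray(sim_matrix, dtype=float)
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 compounds for leave-one-out")
    if ids is None:
        ids = [str(i) for i in range(n)]
    preds, truths = [], []
    for i in range(n):
        mask = np.arange(n) != i
        res = istknn_predict_from_sims(S[i, mask], y[mask], params,
                                       [ids[j] for j in range(n) if j != i])
        if res.prediction is not None:
            preds.append(res.prediction)
            truths.append(y[i])
    coverage = len(preds) / n
    if not preds:
        return {"r2": float("nan"), "mae": float("nan"), "rmse": float("nan"), "coverage": 0.0}
    r2, mae, rmse = _regression_summary(np.array(preds), np.array(truths))
    return {"r2": r2, "mae": mae, "rmse": rmse, "coverage": coverage}


def _evaluate_on(sim_rows, y_true, values_train, params, train_ids=None) -> dict:
    preds, truths = [], []
    for i in range(len(y_true)):
        res = istknn_predict_from_sims(sim_rows[i], values_train, params, train_ids)
        if res.prediction is not None:
            preds.append(res.prediction)
            truths.append(y_true[i])
    coverage = len(preds) / len(y_true)
    if not preds:
        return {"r2": float("nan"), "mae": float("nan"), "rmse": float("nan"), "coverage": 0.0}
    r2, mae, rmse = _regression_summary(np.array(preds), np.array(truths))
    return {"r2": r2, "mae": mae, "rmse": rmse, "coverage": coverage}


def istknn_grid_search(
    grid: list[IstKnnParams],
    sim_train,
    y_train,
    sim_val_train,
    y_val,
    min_coverage: float = 0.85,
    preselect: bool = True,
) -> tuple[IstKnnParams, dict]:
    """Select read-across parameters by LOO pre-selection + validation RMSE.

    ``sim_train`` is the training-pool self-similarity matrix, ``sim_val_train``
    the (validation x training) similarity block.  Candidates are first
    restricted to the Pareto-nondominated set over (LOO RMSE, LOO coverage) on
    the training pool; among those, the winner has the best validation RMSE
    subject to a validation coverage floor (default 0.85).  If no candidate
    reaches the floor, the best-coverage candidate is returned with a warning.
    Ties break deterministically: lower RMSE, then higher coverage, then grid
    order.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    loo = [istknn_loo_cv(sim_train, y_train, p) for p in grid]
    if preselect and len(grid) > 1:
        keep = []
        for i, mi in enumerate(loo):
            if mi["coverage"] == 0:
                continue
            dominated = any(
                mj["coverage"] > 0
                and mj["rmse"] <= mi["rmse"] and mj["coverage"] >= mi["coverage"]
                and (mj["rmse"] < mi["rmse"] or mj["coverage"] > mi["coverage"])
                for j, mj in enumerate(loo) if j != i
            )
            if not dominated:
                keep.append(i)
        pool = keep if keep else list(range(len(grid)))
    else:
        pool = list(range(len(grid)))
    evals = {i: _evaluate_on(np.asarray(sim_val_train), np.asarray(y_val, float),
                             np.asarray(y_train, float), grid[i]) for i in pool}
    eligible = [i for i in pool if evals[i]["coverage"] >= min_coverage
                and not math.isnan(evals[i]["rmse"])]
    if eligible:
        best = min(eligible, key=lambda i: (evals[i]["rmse"], -evals[i]["coverage"], pool.index(i)))
    else:
        logger.warning("no parameter setting reaches coverage %.2f; returning best coverage", min_coverage)
        best = max(pool, key=lambda i: (evals[i]["coverage"], -pool.index(i)))
    return grid[best], evals[best]
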