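"""Applicability-domain (AD) constructions and the coverage/performance tuner.

Five AD constructions decide, per query compound, whether a model's
prediction should be trusted:

* **distance** — the mean Manhattan distance to the k nearest training
  compounds must not exceed a percentile threshold T_D of the training
  distribution (each training compound scored against its k nearest *other*
  training compounds);
* **confidence** — the agreeing-tree fraction of a forest must reach T_C;
* **error** — the error model's predicted absolute error must not exceed a
  percentile threshold T_E of the training predicted-error distribution;
* **dummy matrix** — a classifier is trained to tell real training rows from
  a column-permuted mirror; queries classified as "dummy" are out of AD;
* **outlier similarity** — a query closer (top-3 mean Tanimoto) to the
  flagged response outliers than to the cleaned training set is out of AD.

Thresholds compare non-strictly (a value exactly at the threshold stays in
AD).  Percentiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.ensemble import RandomForestClassifier

from .similarity import BinaryFingerprint, tanimoto

logger = logging.getLogger(__name__)

__all__ = [
    "AdParams",
    "AdFlags",
    "distance_percentile_ad",
    "confidence_ad",
    "error_percentile_ad",
    "dummy_matrix_ad",
    "outlier_similarity_ad",
    "tune_ad",
]

#: Grids used when sweeping the AD parameters.
DISTANCE_PERCENTILES = (100.0, 97.5, 95.0, 90.0)
ERROR_PERCENTILES = (100.0, 90.0, 75.0, 65.0)
CONFIDENCE_GRID_BINARY = (0.60, 0.65, 0.70, 0.75)
CONFIDENCE_GRID_MULTICLASS = (0.30, 0.40, 0.50, 0.60, 0.70)


@dataclass(frozen=True)
class AdParams:
    """One combination of tunable AD thresholds."""

    k: int = 1
    t_d_percentile: float = 100.0
    t_e_percentile: float = 100.0
    t_c: float = 0.0


@dataclass(frozen=True)
class AdFlags:
    """Per-sample in-AD booleans with the method tag and threshold used."""

    in_ad: np.ndarray
    method: str
    threshold: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "in_ad", np.asarray(self.in_ad, dtype=bool))

    @property
    def coverage(self) -> float:
        return float(self.in_ad.mean()) if self.in_ad.size else 0.0


def _mean_knn_distance(D: np.ndarray, k: int) -> np.ndarray:
    """Row-wise mean distance to the k nearest columns."""
    return np.sort(D, axis=1)[:, :k].mean(axis=1)


def distance_percentile_ad(train, query, k: int = 1, percentile: float = 95.0) -> AdFlags:
    """Distance-based AD with a training-percentile threshold T_D.

    Training compounds are scored against their k nearest *other* training
    compounds; queries against their k nearest training compounds.  A query
    is in AD iff its mean distance <= T_D.
    """
    train = np.asarray(train, dtype=float)
    query = np.asarray(query, dtype=float)
    n = train.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the training-set size")
    D_tt = cdist(train, train, metric="cityblock")
    np.fill_diagonal(D_tt, np.inf)  # a training compound is not its own neighbor
    train_means = _mean_knn_distance(D_tt, k)
    t_d = float(np.percentile(train_means, percentile))
    query_means = _mean_knn_distance(cdist(query, train, metric="cityblock"), k)
    return AdFlags(query_means <= t_d, "distance", t_d)


def confidence_ad(confidences, t_c: float) -> AdFlags:
    """Confidence-based AD: in AD iff the forest confidence >= T_C."""
    conf = np.asarray(confidences, dtype=float)
    return AdFlags(conf >= t_c, "confidence", t_c)


def error_percentile_ad(train_pred_errors, query_pred_errors, percentile: float = 100.0) -> AdFlags:
    """Error-model AD: query in AD iff its predicted error <= T_E."""
    tr = np.asarray(train_pred_errors, dtype=float)
    qu = np.asarray(query_pred_errors, dtype=float)
    if (tr < 0).any() or (qu < 0).any():
        raise ValueError("predicted errors must be non-negative")
    t_e = float(np.percentile(tr, percentile))
    return AdFlags(qu <= t_e, "error", t_e)


def dummy_matrix_ad(train, query, seed: int = 0, classifier=None) -> AdFlags:
    """Mirror-matrix AD: reject queries a classifier calls "dummy".

    Each training column is independently permuted across rows to build a
    mirror matrix that keeps marginal distributions but destroys the joint
    structure; a forest learns real vs dummy and queries predicted real are
    in AD.
    """
    train = np.asarray(train, dtype=float)
    query = np.asarray(query, dtype=float)
    if train.shape[1] < 2:
        raise ValueError("need at least 2 descriptor columns")
    rng = np.random.default_rng(seed)
    mirror = np.column_stack([rng.permutation(train[:, j]) for j in range(train.shape[1])])
    X = np.vstack([train, mirror])
    y = np.array([1] * train.shape[0] + [0] * train.shape[0])
    clf = classifier or RandomForestClassifier(n_estimators=200, random_state=seed)
    clf.fit(X, y)
    return AdFlags(clf.predict(query) == 1, "dummy", 0.5)


def outlier_similarity_ad(query_fps, outlier_fps, inlier_fps) -> AdFlags:
    """Outlier-similarity AD on fingerprints.

    A query is out of AD iff its mean Tanimoto similarity to its three most
    similar flagged outliers exceeds that to its three most similar cleaned
    training compounds.
    """
    if len(outlier_fps) < 3 or len(inlier_fps) < 3:
        raise ValueError("need at least 3 fingerprints in each reference set")

    def top3_mean(q: BinaryFingerprint, refs) -> float:
        sims = sorted((tanimoto(q, r) for r in refs), reverse=True)
        return float(np.mean(sims[:3]))

    flags = [top3_mean(q, outlier_fps) <= top3_mean(q, inlier_fps) for q in query_fps]
    return AdFlags(np.array(flags), "outlier-sim", float("nan"))


def tune_ad(
    combinations: list[AdParams],
    performance_fn,
    coverage_floor: float = 0.70,
    higher_is_better: bool = False,
) -> AdParams:
    """Pick AD thresholds by the coverage/performance trade-off.

    ``performance_fn(params) -> (metric, coverage)``.  The Pareto-nondominated
    set over (performance, coverage) is computed first; among it the
    best-performing combination with coverage >= the floor wins.  If none
    reaches the floor the best-coverage combination is returned with a
    warning.  Deterministic: ties break by input order, and the result is
    invariant to reordering of ``combinations``.
    """
    if not combinations:
        raise ValueError("no AD combinations to tune")
    evals = [performance_fn(p) for p in combinations]
    sign = 1.0 if higher_is_better else -1.0
    scored = [(sign * m, c) for m, c in evals]

    def dominated(i: int) -> bool:
        mi, ci = scored[i]
        return any(
            (mj >= mi and cj >= ci) and (mj > mi or cj > ci)
            for j, (mj, cj) in enumerate(scored) if j != i
        )

    front = [i for i in range(len(combinations)) if not dominated(i)]
    eligible = [i for i in front if scored[i][1] >= coverage_floor]
    key = lambda i: (-scored[i][0], -scored[i][1], _params_key(combinations[i]))
    if eligible:
        return combinations[min(eligible, key=key)]
    logger.warning("no AD combination reaches coverage %.2f; returning best coverage", coverage_floor)
    return combinations[min(range(len(combinations)),
                            key=lambda i: (-scored[i][1], _params_key(combinations[i])))]


def _params_key(p: AdParams) -> tuple:
    return (p.k, p.t_d_percentile, p.t_e_percentile, p.t_c)
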