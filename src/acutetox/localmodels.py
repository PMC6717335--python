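"""On-the-fly local modeling: per-target neighbor selection + small ensembles.

For each target compound a local group of 20-50 structurally similar
training compounds is assembled from two fingerprint similarities (PubChem
family >= 0.80 and Extended family >= 0.70 by default).  Compounds above
both thresholds are taken first; if fewer than 20 qualify the group is
filled by best average rank across the two similarity orderings, and if
more than 50 qualify only the best 50 by average rank are kept.

A roster of base learners (linear/nearest-centroid model, forest,
gradient-boosted trees, kNN) is fitted on the local group and their outputs
combined: regression predictions are averaged after discarding any that fall
more than 10% of the training-value span outside the training range;
classification uses a majority vote with ties resolved to the class least
represented in the training set (in practice the most toxic class).

The applicability-domain measure (ADM, 1-5) comes from the mean PubChem and
Extended similarities of the local group; ADM >= 2 is in-AD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .similarity import adm_score

logger = logging.getLogger(__name__)

__all__ = ["LocalPrediction", "aiqsar_select_neighbors", "aiqsar_predict", "default_learners"]


@dataclass(frozen=True)
class LocalPrediction:
    """Outcome of one local-model prediction."""

    value: float | str | None
    neighbor_idx: tuple[int, ...]
    adm: int
    per_learner: tuple
    reason: str = "OK"  # OK | ALL_DISCARDED


def aiqsar_select_neighbors(
    sim_pubchem,
    sim_extended,
    t_pubchem: float = 0.80,
    t_extended: float = 0.70,
    n_min: int = 20,
    n_max: int = 50,
) -> np.ndarray:
    """Select the local group from two per-training-compound similarity vectors.

    Returns training indices, most useful first.  Average rank = mean of the
    two descending-similarity ranks, ties broken by index.
    """
    sp = np.asarray(sim_pubchem, dtype=float)
    se = np.asarray(sim_extended, dtype=float)
    if sp.shape != se.shape:
        raise ValueError("similarity vectors must align")
    n = sp.size
    if n < n_min:
        raise ValueError(f"training pool ({n}) smaller than n_min ({n_min})")
    # rank 0 = most similar; average the two ranks
    rank_p = np.empty(n)
    rank_p[np.argsort(-sp, kind="stable")] = np.arange(n)
    rank_e = np.empty(n)
    rank_e[np.argsort(-se, kind="stable")] = np.arange(n)
    avg_rank = (rank_p + rank_e) / 2.0
    order = sorted(range(n), key=lambda i: (avg_rank[i], i))
    above = [i for i in order if sp[i] >= t_pubchem and se[i] >= t_extended]
    if len(above) >= n_min:
        return np.array(above[:n_max], dtype=int)
    fill = [i for i in order if i not in set(above)]
    return np.array((above + fill)[:n_min], dtype=int)


def default_learners(task: str) -> list[tuple[str, object]]:
    """The pluggable base-learner roster for the local engine."""
    if task == "regression":
        from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
        from sklearn.linear_model import Ridge
        from sklearn.neighbors import KNeighborsRegressor

        return [
            ("linear", Ridge()),
            ("forest", RandomForestRegressor(n_estimators=100, random_state=0)),
            ("gbt", GradientBoostingRegressor(random_state=0)),
            ("knn", KNeighborsRegressor(n_neighbors=3)),
        ]
    if task == "classification":
        from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
        from sklearn.neighbors import KNeighborsClassifier, NearestCentroid

        return [
            ("centroid", NearestCentroid()),
            ("forest", RandomForestClassifier(n_estimators=100, random_state=0)),
            ("gbt", GradientBoostingClassifier(random_state=0)),
            ("knn", KNeighborsClassifier(n_neighbors=3)),
        ]
    raise ValueError("task must be 'regression' or 'classification'")


def aiqsar_predict(
    target_x,
    neighbor_X,
    neighbor_y,
    task: str,
    learners: list[tuple[str, object]] | None = None,
    ts_values=None,
    ts_class_counts: dict | None = None,
    class_order: tuple[str, ...] = ("positive", "negative"),
    sim_pubchem_mean: float = 1.0,
    sim_extended_mean: float = 1.0,
    range_slack: float = 0.10,
    neighbor_idx: tuple[int, ...] = (),
) -> LocalPrediction:
    """Fit the learner roster on the local group and combine their outputs.

    ``ts_values`` (regression) are the global training values defining the
    admissible output range; ``ts_class_counts`` (classification) supply the
    tie-break.  ``range_slack`` is the fraction of the training span by which
    a learner output may exceed the range before being discarded.
    """
    X = np.asarray(neighbor_X, dtype=float)
    y = np.asarray(neighbor_y)
    x = np.asarray(target_x, dtype=float).reshape(1, -1)
    if learners is None:
        learners = default_learners(task)
    adm = adm_score(sim_pubchem_mean, sim_extended_mean)
    outputs = []
    for name, est in learners:
        try:
            est.fit(X, y)
            outputs.append((name, est.predict(x)[0]))
        except Exception as exc:  # a degenerate local group can break a learner
            logger.warning("local learner %s failed: %s", name, exc)
    if not outputs:
        return LocalPrediction(None, tuple(neighbor_idx), adm, (), "ALL_DISCARDED")
    if task == "regression":
        ref = np.asarray(ts_values if ts_values is not None else y, dtype=float)
        lo, hi = float(ref.min()), float(ref.max())
        slack = range_slack * (hi - lo)
        kept = [v for _, v in outputs if lo - slack <= v <= hi + slack]
        if not kept:
            return LocalPrediction(None, tuple(neighbor_idx), adm, tuple(outputs), "ALL_DISCARDED")
        return LocalPrediction(float(np.mean(kept)), tuple(neighbor_idx), adm, tuple(outputs))
    # classification: majority vote, ties -> least represented class in TS
    votes: dict = {}
    for _, label in outputs:
        votes[label] = votes.get(label, 0) + 1
    top = max(votes.values())
    tied = sorted(lab for lab, c in votes.items() if c == top)
    if len(tied) == 1:
        winner = tied[0]
    else:
        counts = ts_class_counts or {}
        toxic_rank = {lab: i for i, lab in enumerate(class_order)}
        winner = min(tied, key=lambda lab: (counts.get(lab, 0),
                                            toxic_rank.get(lab, len(toxic_rank))))
    return LocalPrediction(winner, tuple(neighbor_idx), adm, tuple(outputs))
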