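"""PF/CS consensus integration, reliability thresholds and Pareto selection.

Regression consensus averages the in-AD predictions of the member models
and attaches the *prediction fraction* PF = (in-AD members) / (all members);
classification consensus takes a majority vote over in-AD labels and
attaches the *consensus score* CS = agreeing votes - disagreeing votes
(exact ties abstain).  Both indices grade prediction reliability: a
threshold on PF (or CS) defines the integrated model's applicability
domain, and stratifying external error by PF level shows low-PF samples
carrying most of the large errors.

Model selection across single and integrated models uses the Pareto front
over (performance, coverage): a model is retained iff no other model is at
least as good on both axes and strictly better on one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import regression_metrics

__all__ = [
    "ABSTAIN",
    "IntegratedPrediction",
    "integrate_regression",
    "integrate_classification",
    "integrate_ledger",
    "apply_reliability_threshold",
    "pf_error_report",
    "ParetoPoint",
    "pareto_front",
]

ABSTAIN = "ABSTAIN"


@dataclass(frozen=True)
class IntegratedPrediction:
    """Consensus output for one sample: value/label (or abstention) + PF or CS."""

    sample_id: str
    value: float | str | None
    pf: float | None = None
    cs: int | None = None

    @property
    def abstained(self) -> bool:
        return self.value is None


def integrate_regression(values, in_ad, n_models: int | None = None,
                         sample_id: str = "") -> IntegratedPrediction:
    """Unweighted mean of in-AD member predictions with PF attached.

    ``n_models`` defaults to the number of members passed; with no in-AD
    member the consensus abstains at PF 0.
    """
    values = np.asarray(values, dtype=float)
    in_ad = np.asarray(in_ad, dtype=bool)
    if values.shape != in_ad.shape:
        raise ValueError("values and in_ad must align")
    if n_models is None:
        n_models = values.size
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    contributing = values[in_ad]
    if contributing.size == 0:
        return IntegratedPrediction(sample_id, None, pf=0.0)
    pf = contributing.size / n_models
    return IntegratedPrediction(sample_id, float(contributing.mean()), pf=pf)


def integrate_classification(labels, in_ad, sample_id: str = "") -> IntegratedPrediction:
    """Majority vote over in-AD member labels with CS attached.

    CS = (votes for the majority label) - (votes against it); an exact tie
    between top labels returns an abstention with no CS.
    """
    labels = list(labels)
    in_ad = np.asarray(in_ad, dtype=bool)
    if len(labels) != in_ad.size:
        raise ValueError("labels and in_ad must align")
    votes = [lab for lab, ok in zip(labels, in_ad) if ok]
    if not votes:
        return IntegratedPrediction(sample_id, None)
    counts: dict = {}
    for lab in votes:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == top]
    if len(winners) > 1:
        return IntegratedPrediction(sample_id, None)
    winner = winners[0]
    cs = counts[winner] - (len(votes) - counts[winner])
    return IntegratedPrediction(sample_id, winner, cs=cs)


def integrate_ledger(ledger: pd.DataFrame, mode: str = "regression",
                     n_models: int | None = None) -> list[IntegratedPrediction]:
    """Integrate a tidy prediction ledger (sample_id, model_id, prediction, in_ad)."""
    required = {"sample_id", "model_id", "prediction", "in_ad"}
    if not required <= set(ledger.columns):
        raise ValueError(f"ledger must contain columns {sorted(required)}")
    if n_models is None:
        n_models = ledger["model_id"].nunique()
    out = []
    for sid, grp in ledger.groupby("sample_id", sort=True):
        if mode == "regression":
            out.append(integrate_regression(
                grp["prediction"].to_numpy(float), grp["in_ad"].to_numpy(bool),
                n_models=n_models, sample_id=str(sid)))
        else:
            out.append(integrate_classification(
                grp["prediction"].tolist(), grp["in_ad"].to_numpy(bool), sample_id=str(sid)))
    return out


def apply_reliability_threshold(integrated, threshold: float, index: str = "pf"):
    """In-integrated-AD flags: PF (or CS) >= threshold, abstentions always out.

    Returns (boolean flags aligned with ``integrated``, coverage).
    """
    flags = []
    for p in integrated:
        score = getattr(p, index)
        flags.append(score is not None and not p.abstained and score >= threshold)
    arr = np.array(flags, dtype=bool)
    return arr, float(arr.mean()) if arr.size else 0.0


def pf_error_report(integrated, truth, levels=(0.25, 0.5, 0.75, 1.0)) -> pd.DataFrame:
    """Per-PF-level error stratification of a regression consensus.

    For each exact PF level: R2/MAE/RMSE of the samples at that level, the
    count, the fraction of all predicted samples, and the fraction with
    absolute error >= 1 log unit.
    """
    truth = np.asarray(truth, dtype=float)
    if len(integrated) != truth.size:
        raise ValueError("integrated predictions and truth must align")
    predicted = [(p, t) for p, t in zip(integrated, truth) if not p.abstained]
    total = len(predicted)
    rows = []
    for level in levels:
        sel = [(p.value, t) for p, t in predicted if np.isclose(p.pf, level)]
        if not sel:
            rows.append({"pf": level, "r2": np.nan, "mae": np.nan, "rmse": np.nan,
                         "n": 0, "fraction": 0.0, "frac_abs_error_ge_1": np.nan})
            continue
        pred = np.array([v for v, _ in sel])
        tr = np.array([t for _, t in sel])
        m = regression_metrics(pred, tr)
        abs_err = np.abs(pred - tr)
        rows.append({
            "pf": level, "r2": m["r2"], "mae": m["mae"], "rmse": m["rmse"],
            "n": len(sel), "fraction": len(sel) / total if total else 0.0,
            "frac_abs_error_ge_1": float(np.mean(abs_err >= 1.0)),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ParetoPoint:
    """A model's (performance, coverage) location for Pareto selection."""

    tag: str
    performance: float
    coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")


def pareto_front(points: list[ParetoPoint], minimize_performance: bool = True) -> list[ParetoPoint]:
    """Nondominated subset under weak dominance, in stable input order.

    A point is dominated iff another point is at least as good on both axes
    and strictly better on one (coverage is always maximized; the
    performance sense is configurable).  Duplicated points are all retained.
    """
    if not points:
        raise ValueError("need at least one point")
    sign = -1.0 if minimize_performance else 1.0
    vals = [(sign * p.performance, p.coverage) for p in points]

    def dominated(i: int) -> bool:
        mi, ci = vals[i]
        return any(
            (mj >= mi and cj >= ci) and (mj > mi or cj > ci)
            for j, (mj, cj) in enumerate(vals) if j != i
        )

    return [p for i, p in enumerate(points) if not dominated(i)]
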