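"""Descriptor-matrix pruning and train-anchored [0, 1] normalization.

The pruning rules applied to a training descriptor matrix, in order:

1. drop any column with at least one missing value;
2. drop constant and semi-constant columns (standard deviation < 0.01);
3. among remaining pairs with absolute correlation > 0.95, iteratively drop
   the descriptor with the highest mean absolute correlation to all other
   remaining columns, until no pair exceeds the cut;
4. record per-column (min, max) so external data can be scaled with the
   training scheme — values outside [0, 1] are preserved, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PreprocessScheme", "DescriptorPruner", "prune_descriptors", "apply_scheme"]


@dataclass(frozen=True)
class PreprocessScheme:
    """Surviving columns plus their training (min, max) ranges."""

    columns: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    sd_min: float = 0.01
    corr_max: float = 0.95

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.mins) or len(self.columns) != len(self.maxs):
            raise ValueError("columns, mins and maxs must align")
        if (np.asarray(self.maxs) < np.asarray(self.mins)).any():
            raise ValueError("max must be >= min per column")


class DescriptorPruner:
    """Transformer applying the pruning + normalization pipeline.

    Fitted on training rows only; ``transform`` scales any matrix containing
    the surviving columns with the training min/max (zero-range columns map
    to 0; out-of-range values are not clipped).
    """

    def __init__(self, sd_min: float = 0.01, corr_max: float = 0.95) -> None:
        self.sd_min = sd_min
        self.corr_max = corr_max

    def get_params(self, deep: bool = True) -> dict:
        return {"sd_min": self.sd_min, "corr_max": self.corr_max}

    def set_params(self, **params) -> "DescriptorPruner":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X: pd.DataFrame, y=None) -> "DescriptorPruner":
        X = _as_frame(X)
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit the pruning scheme")
        keep = [c for c in X.columns if not X[c].isna().any()]
        X = X[keep]
        sds = X.std(ddof=1)
        keep = [c for c in X.columns if sds[c] >= self.sd_min]
        X = X[keep]
        if X.shape[1] == 0:
            raise ValueError("all descriptor columns were pruned")
        cols = list(X.columns)
        corr = X.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        alive = list(range(len(cols)))
        while True:
            sub = corr[np.ix_(alive, alive)]
            if sub.size == 0 or np.nanmax(sub) <= self.corr_max:
                break
            # mean |r| with all other remaining columns; drop the worst offender
            means = np.nanmean(sub, axis=1)
            offenders = np.argwhere(sub > self.corr_max)
            cand = sorted({int(i) for pair in offenders for i in pair})
            worst = max(cand, key=lambda i: (means[i], -i))
            alive.pop(worst)
            if not alive:
                raise ValueError("all descriptor columns were pruned")
        survivors = [cols[i] for i in alive]
        kept = X[survivors]
        self.scheme_ = PreprocessScheme(
            columns=tuple(survivors),
            mins=kept.min().to_numpy(dtype=float),
            maxs=kept.max().to_numpy(dtype=float),
            sd_min=self.sd_min,
            corr_max=self.corr_max,
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "scheme_"):
            raise RuntimeError("DescriptorPruner is not fitted")
        return apply_scheme(_as_frame(X), self.scheme_)

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def prune_descriptors(
    train: pd.DataFrame, sd_min: float = 0.01, corr_max: float = 0.95
) -> tuple[pd.DataFrame, PreprocessScheme]:
    """Functional form: prune + normalize a training matrix, return the scheme."""
    pruner = DescriptorPruner(sd_min=sd_min, corr_max=corr_max)
    out = pruner.fit_transform(train)
    return out, pruner.scheme_


def apply_scheme(matrix: pd.DataFrame, scheme: PreprocessScheme) -> pd.DataFrame:
    """Scale a matrix with a training scheme: x' = (x - min) / (max - min)."""
    matrix = _as_frame(matrix)
    missing = [c for c in scheme.columns if c not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks scheme columns: {missing}")
    sub = matrix[list(scheme.columns)].astype(float)
    span = scheme.maxs - scheme.mins
    out = sub.copy()
    for j, c in enumerate(scheme.columns):
        if span[j] == 0:
            out[c] = 0.0
        else:
            out[c] = (sub[c] - scheme.mins[j]) / span[j]
    return out
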