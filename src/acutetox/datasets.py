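"""Chemical-record ingestion, endpoint derivation and dataset splitting.

The modeled quantity is the rat acute oral LD50 (mg/kg body weight).  Five
endpoints are derived from it:

* ``LOG_MMOL`` — continuous log10 of the dose in mmol/kg, the regression
  target;
* ``VT`` ("very toxic") — binary, positive iff LD50 < 50 mg/kg;
* ``NT`` ("non-toxic") — binary, positive iff LD50 > 2000 mg/kg;
* ``EPA`` — the U.S. EPA 4-category hazard scheme;
* ``GHS`` — the UN GHS 5-category hazard scheme.

Category boundaries are implemented exactly as the regulatory schemes state
them, including the (intentional) inclusivity mismatch between EPA Category I
(LD50 <= 50) and the vT positive class (LD50 < 50).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Descriptors import MolWt
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "ChemicalRecord",
    "EndpointScheme",
    "EPA_SCHEME",
    "GHS_SCHEME",
    "to_log_mmol",
    "categorize",
    "aggregate_duplicates",
    "pca_outlier_flags",
    "kmeans_stratified_split",
    "load_chemical_table",
    "derive_endpoints",
]


@dataclass
class ChemicalRecord:
    """One compound: identifier, structure and experimental LD50."""

    id: str
    smiles: str
    ld50_mg_per_kg: float
    cas: str | None = None
    mw: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.ld50_mg_per_kg <= 0:
            raise ValueError(f"LD50 must be positive, got {self.ld50_mg_per_kg}")
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"molecular weight must be positive, got {self.mw}")


@dataclass(frozen=True)
class EndpointScheme:
    """An ordered LD50 banding scheme.

    ``cuts`` are strictly increasing boundary doses in mg/kg; ``upper_inclusive``
    says, per cut, whether a value exactly at the cut belongs to the band below
    it.  ``labels`` has one more entry than ``cuts``.
    """

    name: str
    cuts: tuple[float, ...]
    labels: tuple[str, ...]
    upper_inclusive: tuple[bool, ...] = field(default=())

    def __post_init__(self) -> None:
        if list(self.cuts) != sorted(set(self.cuts)):
            raise ValueError("cuts must be strictly increasing")
        if len(self.labels) != len(self.cuts) + 1:
            raise ValueError("need exactly one more label than cuts")
        if not self.upper_inclusive:
            object.__setattr__(self, "upper_inclusive", tuple(True for _ in self.cuts))
        if len(self.upper_inclusive) != len(self.cuts):
            raise ValueError("one inclusivity flag per cut required")


#: EPA hazard scheme: I <=50, II (50, 500], III (500, 5000], IV > 5000.
EPA_SCHEME = EndpointScheme(
    name="EPA",
    cuts=(50.0, 500.0, 5000.0),
    labels=("I", "II", "III", "IV"),
    upper_inclusive=(True, True, True),
)

#: GHS hazard scheme: I <=5, II (5, 50], III (50, 300], IV (300, 2000], V > 2000.
GHS_SCHEME = EndpointScheme(
    name="GHS",
    cuts=(5.0, 50.0, 300.0, 2000.0),
    labels=("I", "II", "III", "IV", "V"),
    upper_inclusive=(True, True, True, True),
)

_SCHEMES = {"EPA": EPA_SCHEME, "GHS": GHS_SCHEME}


def to_log_mmol(ld50_mg_per_kg: float, mw: float) -> float:
    """Convert an LD50 in mg/kg to log10(mmol/kg) given the molecular weight.

    mg/kg divided by g/mol equals mmol/kg, so the conversion is
    ``log10(ld50 / mw)``.
    """
    if ld50_mg_per_kg <= 0 or mw <= 0:
        raise ValueError("LD50 and molecular weight must both be positive")
    return math.log10(ld50_mg_per_kg / mw)


def categorize(ld50_mg_per_kg: float, scheme: str | EndpointScheme) -> str:
    """Map an LD50 value onto a categorical endpoint.

    ``scheme`` may be ``"VT"``, ``"NT"``, an :class:`EndpointScheme`, or the
    names ``"EPA"`` / ``"GHS"``.  Binary endpoints return ``"positive"`` /
    ``"negative"``: vT is positive iff LD50 < 50 (50 itself is negative), nT is
    positive iff LD50 > 2000 (2000 itself is negative).
    """
    if ld50_mg_per_kg <= 0:
        raise ValueError("LD50 must be positive")
    if isinstance(scheme, str):
        key = scheme.upper()
        if key == "VT":
            return "positive" if ld50_mg_per_kg < 50.0 else "negative"
        if key == "NT":
            return "positive" if ld50_mg_per_kg > 2000.0 else "negative"
        try:
            scheme = _SCHEMES[key]
        except KeyError:
            raise ValueError(f"unknown endpoint scheme {scheme!r}") from None
    for cut, label, inc in zip(scheme.cuts, scheme.labels, scheme.upper_inclusive):
        if ld50_mg_per_kg < cut or (inc and ld50_mg_per_kg == cut):
            return label
    return scheme.labels[-1]


def _desalted_canonical(smiles: str) -> tuple[str, float] | None:
    """Canonical SMILES of the largest organic component, plus its MW.

    Returns ``None`` for unparseable input.  Desalting keeps the fragment with
    the most heavy atoms (ties: higher MW) before canonicalization, since
    duplicate entries typically differ only by counterion.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    best = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), MolWt(m)))
    return Chem.MolToSmiles(best), MolWt(best)


_AGG = {
    "geometric_mean": lambda v: float(np.exp(np.mean(np.log(v)))),
    "median": lambda v: float(np.median(v)),
    "arithmetic_mean": lambda v: float(np.mean(v)),
}


def aggregate_duplicates(
    records: Sequence[ChemicalRecord], policy: str = "geometric_mean"
) -> tuple[list[ChemicalRecord], int]:
    """Merge records sharing a desalted canonical structure.

    The default policy, the geometric mean of the mg/kg values, is the
    arithmetic mean in log space — the scale all regression modeling runs on.
    Unparseable SMILES are dropped with a warning.  Returns the aggregated
    records and the number of merges performed.
    """
    if policy not in _AGG:
        raise ValueError(f"unknown aggregation policy {policy!r}")
    groups: dict[str, list[tuple[ChemicalRecord, float]]] = {}
    order: list[str] = []
    for rec in records:
        parsed = _desalted_canonical(rec.smiles)
        if parsed is None:
            logger.warning("dropping record %s: unparseable SMILES %r", rec.id, rec.smiles)
            continue
        canon, mw = parsed
        if canon not in groups:
            groups[canon] = []
            order.append(canon)
        groups[canon].append((rec, mw))
    out: list[ChemicalRecord] = []
    n_merges = 0
    for canon in order:
        members = groups[canon]
        first, mw = members[0]
        if len(members) == 1:
            out.append(
                ChemicalRecord(
                    id=first.id, smiles=canon, ld50_mg_per_kg=first.ld50_mg_per_kg,
                    cas=first.cas, mw=mw, source=first.source,
                )
            )
            continue
        n_merges += len(members) - 1
        value = _AGG[policy]([r.ld50_mg_per_kg for r, _ in members])
        out.append(
            ChemicalRecord(id=first.id, smiles=canon, ld50_mg_per_kg=value,
                           cas=first.cas, mw=mw, source=first.source)
        )
    return out, n_merges


def pca_outlier_flags(
    descriptors: np.ndarray, n_components: int = 2, z_cut: float = 6.0
) -> np.ndarray:
    """Flag structural outliers on the first two principal components.

    A compound is flagged iff the absolute standardized score on PC1 or PC2
    exceeds ``z_cut``.  The default cut (6 SD) encodes an extreme-tail rule.
    """
    X = np.asarray(descriptors, dtype=float)
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    if X.ndim != 2 or X.shape[0] < n_components:
        raise ValueError("need at least as many rows as components")
    if np.isnan(X).any():
        raise ValueError("descriptor matrix must be complete (no missing values)")
    scores = PCA(n_components=n_components).fit_transform(X)
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = np.abs(scores / sd)
    return (z > z_cut).any(axis=1)


def kmeans_stratified_split(
    fingerprints: np.ndarray,
    activity: np.ndarray,
    frac: float = 0.8,
    k_clusters: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster-stratified split into internal training (iTS) and validation (iVS).

    K-means runs on the binary fingerprint bits with the activity (scaled to
    [0, 1]) appended, so that the two partitions are analogous both
    structurally and in activity.  Within each cluster ``round(frac * n)``
    records go to the iTS; clusters smaller than 2 go wholly to the iTS.
    Returns (iTS indices, iVS indices), each sorted.
    """
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    F = np.asarray(fingerprints, dtype=float)
    y = np.asarray(activity, dtype=float)
    if F.shape[0] != y.shape[0]:
        raise ValueError("fingerprints and activity length mismatch")
    n = F.shape[0]
    if k_clusters is None:
        k_clusters = max(2, n // 50)
    k_clusters = min(max(1, k_clusters), n)
    span = y.max() - y.min()
    y01 = (y - y.min()) / span if span > 0 else np.zeros_like(y)
    X = np.column_stack([F, y01])
    labels = KMeans(n_clusters=k_clusters, random_state=seed, n_init=10).fit_predict(X)
    rng = np.random.default_rng(seed)
    its: list[int] = []
    ivs: list[int] = []
    for c in range(k_clusters):
        idx = np.flatnonzero(labels == c)
        if idx.size == 0:
            continue
        if idx.size < 2:
            logger.warning("cluster %d has %d record(s); assigned wholly to iTS", c, idx.size)
            its.extend(idx.tolist())
            continue
        n_train = int(round(frac * idx.size))
        n_train = min(max(n_train, 0), idx.size)
        perm = rng.permutation(idx)
        its.extend(perm[:n_train].tolist())
        ivs.extend(perm[n_train:].tolist())
    return np.array(sorted(its), dtype=int), np.array(sorted(ivs), dtype=int)


def load_chemical_table(path) -> list[ChemicalRecord]:
    """Read the input CSV (columns: id, smiles, ld50_mg_per_kg, optional cas/source)."""
    df = pd.read_csv(path, dtype={"id": str})
    required = {"id", "smiles", "ld50_mg_per_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"input CSV missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ChemicalRecord(
                id=str(row.id),
                smiles=str(row.smiles),
                ld50_mg_per_kg=float(row.ld50_mg_per_kg),
                cas=str(row.cas) if "cas" in df.columns and pd.notna(row.cas) else None,
                source=str(row.source) if "source" in df.columns and pd.notna(row.source) else None,
            )
        )
    return records


def derive_endpoints(records: Sequence[ChemicalRecord]) -> pd.DataFrame:
    """Tabulate all five endpoints for a list of records."""
    rows = []
    for rec in records:
        mw = rec.mw
        if mw is None:
            parsed = _desalted_canonical(rec.smiles)
            if parsed is None:
                logger.warning("skipping %s: unparseable SMILES", rec.id)
                continue
            _, mw = parsed
        rows.append(
            {
                "id": rec.id,
                "smiles": rec.smiles,
                "ld50_mg_per_kg": rec.ld50_mg_per_kg,
                "mw": mw,
                "log_mmol": to_log_mmol(rec.ld50_mg_per_kg, mw),
                "vt": categorize(rec.ld50_mg_per_kg, "VT"),
                "nt": categorize(rec.ld50_mg_per_kg, "NT"),
                "epa": categorize(rec.ld50_mg_per_kg, EPA_SCHEME),
                "ghs": categorize(rec.ld50_mg_per_kg, GHS_SCHEME),
            }
        )
    return pd.DataFrame(rows)
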