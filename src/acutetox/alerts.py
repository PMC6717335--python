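"""Structural-alert mining from SMILES by exhaustive fragmentation.

A structural alert (SA) is a substructure whose presence in a molecule is
statistically associated with a toxicity class.  Mining proceeds in three
stages:

1. **fragment enumeration** — every connected fragment obtainable by breaking
   up to ``max_breaks`` acyclic single bonds of a training molecule (ring
   bonds are kept intact to bound the fragment space), encoded as a
   canonical SMARTS pattern;
2. **validation** — each candidate fragment is scored by the likelihood
   ratio LR = (tp / n_target) / (fp / n_other), the ratio of its hit rate in
   the target class to its hit rate in the other class(es); LR is +inf for
   fragments that never hit the other class;
3. **ruleset reduction** — a greedy set cover: the best remaining candidate
   (highest LR, then highest support, then lexicographic SMARTS) is admitted,
   the molecules it matches are removed, and the search repeats until no
   candidate meets the admission thresholds (``min_lr``, ``min_tp``).

Classification applies the ruleset: the label of the matched alert with the
highest LR wins, ties resolve to the more toxic class; a molecule matching
no alert is outside the model's applicability domain (``OUT_OF_AD``).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

from rdkit import Chem

logger = logging.getLogger(__name__)

__all__ = [
    "OUT_OF_AD",
    "StructuralAlert",
    "Ruleset",
    "enumerate_fragments",
    "likelihood_ratio",
    "extract_ruleset",
    "sa_classify",
    "AlertMiner",
]

OUT_OF_AD = "OUT_OF_AD"


@dataclass(frozen=True)
class StructuralAlert:
    """A SMARTS fragment with its class label and validation statistics."""

    smarts: str
    label: str
    lr: float
    tp: int
    fp: int

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0:
            raise ValueError("support counts must be non-negative")
        if math.isinf(self.lr) and self.fp != 0:
            raise ValueError("LR is infinite only when fp == 0")

    def query(self):
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:
            raise ValueError(f"invalid SMARTS {self.smarts!r}")
        return q


@dataclass
class Ruleset:
    """An ordered collection of structural alerts plus class priors.

    ``class_order`` lists labels from most to least toxic and drives the
    conservative tie-break during classification.
    """

    alerts: list[StructuralAlert]
    class_counts: dict[str, int]
    class_order: tuple[str, ...] = ("positive", "negative")

    def __post_init__(self) -> None:
        seen = set()
        for a in self.alerts:
            if a.smarts in seen:
                raise ValueError(f"duplicate SMARTS in ruleset: {a.smarts}")
            seen.add(a.smarts)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"smarts": a.smarts, "label": a.label, "lr": a.lr, "tp": a.tp, "fp": a.fp}
             for a in self.alerts]
        )

    @classmethod
    def from_frame(cls, df, class_counts=None, class_order=("positive", "negative")) -> "Ruleset":
        alerts = [StructuralAlert(r.smarts, r.label, float(r.lr), int(r.tp), int(r.fp))
                  for r in df.itertuples(index=False)]
        return cls(alerts, dict(class_counts or {}), tuple(class_order))


def _breakable_bonds(mol) -> list[int]:
    """Indices of acyclic single (non-ring) bonds."""
    return [
        b.GetIdx() for b in mol.GetBonds()
        if b.GetBondType() == Chem.BondType.SINGLE and not b.IsInRing()
    ]


def enumerate_fragments(
    smiles: str, max_breaks: int = 3, min_atoms: int = 2, max_atoms: int = 18
) -> set[str]:
    """All connected fragments from breaking up to ``max_breaks`` acyclic single bonds.

    Fragments are returned as canonical SMILES usable directly as SMARTS
    queries (aromaticity is preserved because ring bonds are never broken);
    atom counts outside ``[min_atoms, max_atoms]`` are discarded.  With
    ``max_breaks = 0`` only the whole molecule is returned.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    bonds = _breakable_bonds(mol)
    n_atoms = mol.GetNumHeavyAtoms()
    out: set[str] = set()
    if min_atoms <= n_atoms <= max_atoms:
        out.add(Chem.MolToSmiles(mol))
    for r in range(1, max_breaks + 1):
        for combo in itertools.combinations(bonds, r):
            rw = Chem.RWMol(mol)
            pairs = [(mol.GetBondWithIdx(i).GetBeginAtomIdx(),
                      mol.GetBondWithIdx(i).GetEndAtomIdx()) for i in combo]
            for a, b in pairs:
                rw.RemoveBond(a, b)
            for frag in Chem.GetMolFrags(rw.GetMol(), asMols=True, sanitizeFrags=False):
                if min_atoms <= frag.GetNumHeavyAtoms() <= max_atoms:
                    out.add(Chem.MolToSmiles(frag))
    return out


def likelihood_ratio(tp: int, fp: int, n_target: int, n_other: int) -> float:
    """LR = (tp / n_target) / (fp / n_other); +inf when fp = 0 and tp > 0, 0 when tp = 0."""
    if not (0 <= tp <= n_target and 0 <= fp <= n_other):
        raise ValueError("supports must satisfy 0 <= tp <= n_target and 0 <= fp <= n_other")
    if n_target <= 0 or n_other <= 0:
        raise ValueError("class sizes must be positive")
    if tp == 0:
        return 0.0
    if fp == 0:
        return math.inf
    return (tp / n_target) / (fp / n_other)


def _match_mask(query, mols) -> list[bool]:
    return [m.HasSubstructMatch(query) for m in mols]


def extract_ruleset(
    smiles_list,
    labels,
    min_lr: float = 2.0,
    min_tp: int = 4,
    max_breaks: int = 3,
    min_atoms: int = 2,
    max_atoms: int = 18,
    class_order: tuple[str, ...] = ("positive", "negative"),
) -> Ruleset:
    """Mine a reduced ruleset of structural alerts from labeled SMILES.

    Mining runs independently per class label (so alerts for both classes can
    coexist); within a class the greedy set cover above drives admission.
    Likelihood ratios are computed against the full class sizes while support
    is counted on yet-uncovered molecules, so admitted supports never
    overlap.  Deterministic for fixed input order.
    """
    labels = [str(l) for l in labels]
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes to mine alerts")
    mols = []
    kept_labels = []
    for smi, lab in zip(smiles_list, labels):
        m = Chem.MolFromSmiles(smi)
        if m is None:
            logger.warning("skipping unparseable SMILES %r", smi)
            continue
        mols.append(m)
        kept_labels.append(lab)
    class_counts = {c: kept_labels.count(c) for c in classes}
    alerts: list[StructuralAlert] = []
    for target in classes:
        n_target = class_counts[target]
        n_other = len(mols) - n_target
        if n_target == 0 or n_other == 0:
            continue
        # candidate fragments come from target-class molecules only
        candidates: set[str] = set()
        for m, lab in zip(mols, kept_labels):
            if lab == target:
                candidates |= enumerate_fragments(
                    Chem.MolToSmiles(m), max_breaks, min_atoms, max_atoms
                )
        queries = []
        for smarts in sorted(candidates):
            q = Chem.MolFromSmarts(smarts)
            if q is not None:
                queries.append((smarts, q))
        # precompute the full match matrix once
        matches = {smarts: _match_mask(q, mols) for smarts, q in queries}
        active = [True] * len(mols)
        while True:
            qualifying = []
            for smarts, _ in queries:
                mask = matches[smarts]
                tp = sum(1 for i, m in enumerate(mask)
                         if m and active[i] and kept_labels[i] == target)
                fp = sum(1 for i, m in enumerate(mask)
                         if m and active[i] and kept_labels[i] != target)
                if tp < min_tp:
                    continue
                lr = likelihood_ratio(tp, fp, n_target, n_other)
                if lr < min_lr:
                    continue
                qualifying.append((smarts, lr, tp, fp))
            if not qualifying:
                break
            # best alert: highest LR, then highest support, then lexicographic
            smarts, lr, tp, fp = min(qualifying, key=lambda t: (-t[1], -t[2], t[0]))
            alerts.append(StructuralAlert(smarts=smarts, label=target, lr=lr, tp=tp, fp=fp))
            for i, m in enumerate(matches[smarts]):
                if m:
                    active[i] = False
            active_left = sum(1 for i, a in enumerate(active) if a and kept_labels[i] == target)
            if active_left < min_tp:
                break
    if not alerts:
        logger.warning("no fragment met the admission thresholds; empty ruleset")
    alerts.sort(key=lambda a: (-a.lr, -a.tp, a.smarts))
    return Ruleset(alerts=alerts, class_counts=class_counts, class_order=class_order)


def sa_classify(smiles: str, ruleset: Ruleset) -> str:
    """Classify one molecule with a ruleset; no matching alert -> ``OUT_OF_AD``.

    Among matched alerts the highest-LR label wins; exact LR ties across
    labels resolve to the most toxic class per ``ruleset.class_order``.
    Invariant to query kekulization/atom ordering because matching goes
    through a parsed, sanitized molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles!r}")
    best_by_label: dict[str, float] = {}
    for alert in ruleset.alerts:
        if mol.HasSubstructMatch(alert.query()):
            prev = best_by_label.get(alert.label, -math.inf)
            best_by_label[alert.label] = max(prev, alert.lr)
    if not best_by_label:
        return OUT_OF_AD
    toxic_rank = {lab: i for i, lab in enumerate(ruleset.class_order)}
    return min(
        best_by_label.items(),
        key=lambda kv: (-kv[1], toxic_rank.get(kv[0], len(toxic_rank))),
    )[0]


class AlertMiner:
    """scikit-learn style wrapper around ruleset mining and classification.

    ``fit(smiles, y)`` mines the ruleset; ``predict(smiles)`` applies it,
    returning ``OUT_OF_AD`` for molecules outside the ruleset's domain.
    """

    def __init__(
        self,
        min_lr: float = 2.0,
        min_tp: int = 4,
        max_breaks: int = 3,
        min_atoms: int = 2,
        max_atoms: int = 18,
        class_order: tuple[str, ...] = ("positive", "negative"),
    ) -> None:
        self.min_lr = min_lr
        self.min_tp = min_tp
        self.max_breaks = max_breaks
        self.min_atoms = min_atoms
        self.max_atoms = max_atoms
        self.class_order = class_order

    def get_params(self, deep: bool = True) -> dict:
        return {
            "min_lr": self.min_lr, "min_tp": self.min_tp, "max_breaks": self.max_breaks,
            "min_atoms": self.min_atoms, "max_atoms": self.max_atoms,
            "class_order": self.class_order,
        }

    def set_params(self, **params) -> "AlertMiner":
        for key, value in params.items():
            if not hasattr(self, key):
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self

    def fit(self, X, y) -> "AlertMiner":
        self.ruleset_ = extract_ruleset(
            X, y, min_lr=self.min_lr, min_tp=self.min_tp, max_breaks=self.max_breaks,
            min_atoms=self.min_atoms, max_atoms=self.max_atoms, class_order=self.class_order,
        )
        return self

    def predict(self, X) -> list[str]:
        if not hasattr(self, "ruleset_"):
            raise RuntimeError("AlertMiner is not fitted")
        return [sa_classify(smi, self.ruleset_) for smi in X]
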