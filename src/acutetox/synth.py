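"""Deterministic generators for every fixture the test-suite needs.

Four generators emulate, with known ground truth, the data shapes the
pipeline consumes:

* descriptor matrices with a known (linear or mildly nonlinear) response;
* binary fingerprint populations with cluster structure at a target
  within-cluster Tanimoto similarity;
* labeled SMILES sets with a planted toxicophore determining the class at a
  stated fidelity;
* multi-model prediction ledgers with controlled error SDs, error
  correlations and per-model AD coverages.

All generators are pure functions of their arguments (same spec, same seed
-> identical output).

The SMILES generator builds molecules from a fixed library of rigid
fused-ring scaffolds (13+ heavy atoms, no acyclic single bonds) carrying
one benign decoration and, for planted molecules, a nitrophenyl
toxicophore.  Scaffolds and decorations are assigned round-robin within
each class, so every scaffold and every decoration occurs in both classes;
combined with the rigidity of the scaffolds this guarantees that the only
fragment family separating the classes is the planted toxicophore itself,
which makes alert recovery a property of the construction rather than of a
particular random draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.optimize import brentq

__all__ = [
    "SCAFFOLD_TEMPLATES",
    "BENIGN_DECORATIONS",
    "DEFAULT_TOXICOPHORE",
    "gen_descriptor_dataset",
    "gen_fingerprint_population",
    "gen_planted_alert_smiles",
    "gen_model_ledger",
]

# Rigid fused-ring scaffold templates; "(*)" is the decoration slot and the
# trailing position takes the toxicophore.  All are 13+ heavy atoms with no
# acyclic single bonds: since only acyclic single bonds are ever broken, any
# fragment touching a scaffold atom contains the whole ring system, and a
# fragment joining a scaffold to toxicophore atoms exceeds the default
# fragment-size cap — the planted fragment itself stays the only
# class-separating candidate.
SCAFFOLD_TEMPLATES: tuple[str, ...] = (
    "c1ccc2cc3cc(*)ccc3cc2c1",
    "n1ccc2cc3cc(*)ccc3cc2c1",
    "c1ncc2cc3cc(*)ccc3cc2c1",
    "c1cnc2cc3cc(*)ccc3cc2c1",
    "c1ccc2nc3cc(*)ccc3cc2c1",
    "c1ccc2cc3nc(*)ccc3cc2c1",
    "c1ccc2cc3cc(*)ncc3cc2c1",
    "c1ccc2cc3cc(*)cnc3cc2c1",
    "c1ccc2cc3cc(*)ccc3nc2c1",
    "n1ncc2cc3cc(*)ccc3cc2c1",
    "n1cnc2cc3cc(*)ccc3cc2c1",
    "n1ccc2nc3cc(*)ccc3cc2c1",
    "n1ccc2cc3nc(*)ccc3cc2c1",
    "n1ccc2cc3cc(*)ncc3cc2c1",
    "n1ccc2cc3cc(*)cnc3cc2c1",
    "n1ccc2cc3cc(*)ccc3nc2c1",
    "c1nnc2cc3cc(*)ccc3cc2c1",
    "c1ncc2nc3cc(*)ccc3cc2c1",
    "c1ncc2cc3nc(*)ccc3cc2c1",
    "c1ncc2cc3cc(*)ncc3cc2c1",
    "c1ncc2cc3cc(*)cnc3cc2c1",
    "c1ncc2cc3cc(*)ccc3nc2c1",
    "c1cnc2nc3cc(*)ccc3cc2c1",
    "c1cnc2cc3nc(*)ccc3cc2c1",
    "c1cnc2cc3cc(*)ncc3cc2c1",
    "c1cnc2cc3cc(*)cnc3cc2c1",
)

#: Benign substituents filling the decoration slot (no nitro chemistry).
BENIGN_DECORATIONS: tuple[str, ...] = (
    "C", "CC", "CCC", "CCO", "OC", "O", "N", "C(C)C", "C(=O)C", "Cl",
)

#: The default planted toxicophore: a nitrophenyl group.
DEFAULT_TOXICOPHORE = "c1ccc([N+](=O)[O-])cc1"


@dataclass(frozen=True)
class PlantedAlertSpec:
    """Specification for the planted-toxicophore SMILES generator."""

    n_pos: int = 100
    n_neg: int = 100
    fidelity: float = 1.0
    toxicophore: str = DEFAULT_TOXICOPHORE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.fidelity <= 1.0:
            raise ValueError("fidelity must lie in (0.5, 1]")


def gen_descriptor_dataset(
    n: int,
    p: int,
    n_informative: int = 5,
    effect: np.ndarray | None = None,
    noise_sd: float = 0.5,
    task: str = "regression",
    class_proportions=None,
    nonlinear: bool = False,
    seed: int = 0,
):
    """Descriptor matrix with a known response structure.

    Regression: ``y = X beta + eps``.  Classification: the latent response is
    thresholded at its own quantiles to realize ``class_proportions``.
    Returns ``(X DataFrame, y, truth dict)`` where the truth record carries
    the coefficients, noise SD and any thresholds.
    """
    if n < 1 or p < 1:
        raise ValueError("n and p must be >= 1")
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if effect is None:
        beta = np.zeros(p)
        k = min(n_informative, p)
        beta[:k] = np.linspace(1.0, 0.5, k)
    else:
        beta = np.asarray(effect, dtype=float)
        if beta.size != p:
            raise ValueError("effect vector must have length p")
    latent = X @ beta
    if nonlinear:
        latent = latent + 0.5 * X[:, 0] * X[:, min(1, p - 1)] + 0.5 * (X[:, 0] > 0)
    noise = rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    latent = latent + noise
    cols = [f"d{j}" for j in range(p)]
    frame = pd.DataFrame(X, columns=cols)
    truth = {"beta": beta, "noise_sd": noise_sd, "nonlinear": nonlinear}
    if task == "regression":
        return frame, latent, truth
    if task != "classification":
        raise ValueError("task must be 'regression' or 'classification'")
    props = np.asarray(class_proportions if class_proportions is not None else [0.5, 0.5], float)
    if (props <= 0).any() or not np.isclose(props.sum(), 1.0):
        raise ValueError("class proportions must be positive and sum to 1")
    qs = np.cumsum(props)[:-1]
    thresholds = np.quantile(latent, qs)
    y = np.digitize(latent, thresholds)
    truth["thresholds"] = thresholds
    truth["proportions"] = props
    return frame, y, truth


def _expected_within_tanimoto(f: float, d: float) -> float:
    """Mean Tanimoto of two cluster members at flip probability f, center density d."""
    num = d * (1 - f) ** 2 + (1 - d) * f**2
    den = d * (1 - f**2) + (1 - d) * f * (2 - f)
    return num / den if den > 0 else 1.0


def gen_fingerprint_population(
    n: int, bits: int = 256, n_clusters: int = 4, within_sim: float = 0.6,
    density: float = 0.2, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary fingerprints with cluster structure at a target within-cluster Tanimoto.

    Cluster centers are random at the given bit density; members flip each
    center bit with a probability solved so the expected within-cluster
    Tanimoto equals ``within_sim`` (targets must exceed the random-overlap
    floor of ~1/3).  Returns ``(n x bits uint8 array, cluster ids)``.
    """
    if not 0 < within_sim <= 1:
        raise ValueError("within_sim must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    if within_sim >= 1.0:
        f = 0.0
    else:
        floor = _expected_within_tanimoto(0.5, density)
        if within_sim <= floor:
            raise ValueError(f"within_sim must exceed the random floor {floor:.3f}")
        f = brentq(lambda x: _expected_within_tanimoto(x, density) - within_sim, 1e-9, 0.5)
    centers = (rng.random((n_clusters, bits)) < density).astype(np.uint8)
    labels = np.arange(n) % n_clusters
    flips = (rng.random((n, bits)) < f).astype(np.uint8)
    fps = centers[labels] ^ flips
    return fps, labels


def gen_planted_alert_smiles(spec: PlantedAlertSpec) -> pd.DataFrame:
    """Labeled SMILES with a planted toxicophore at the stated fidelity.

    Positives carry the toxicophore with probability ``fidelity``; negatives
    with probability ``1 - fidelity``.  Every molecule is scaffold +
    decoration (round-robin within each class).  Returns a DataFrame with
    columns id, smiles, label, planted; all SMILES are validated and
    canonicalized, and an invalid assembly raises.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, count in (("positive", spec.n_pos), ("negative", spec.n_neg)):
        p_carry = spec.fidelity if label == "positive" else 1.0 - spec.fidelity
        for i in range(count):
            template = SCAFFOLD_TEMPLATES[i % len(SCAFFOLD_TEMPLATES)]
            dec = BENIGN_DECORATIONS[i % len(BENIGN_DECORATIONS)]
            carry = bool(rng.random() < p_carry)
            smiles = template.replace("(*)", f"({dec})") + (spec.toxicophore if carry else "")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                raise ValueError(f"invalid assembly {smiles!r}")
            rows.append({
                "id": f"{label[:3]}{i:04d}",
                "smiles": Chem.MolToSmiles(mol),
                "label": label,
                "planted": carry,
            })
    return pd.DataFrame(rows)


def gen_model_ledger(
    n_samples: int,
    n_models: int = 4,
    error_sd=0.5,
    ad_coverage=0.9,
    correlation: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulated multi-model prediction ledger with ground truth.

    Per-model errors are multivariate normal with the stated SDs and a common
    pairwise correlation; in-AD indicators are independent Bernoulli draws at
    the stated coverages.  Returns ``(ledger DataFrame, truth vector)``; the
    ledger has columns sample_id, model_id, prediction, in_ad.
    """
    sds = np.broadcast_to(np.asarray(error_sd, float), (n_models,)).copy()
    covs = np.broadcast_to(np.asarray(ad_coverage, float), (n_models,)).copy()
    if ((covs < 0) | (covs > 1)).any():
        raise ValueError("coverages must lie in [0, 1]")
    cov = np.outer(sds, sds) * correlation
    np.fill_diagonal(cov, sds**2)
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n_models))
    except np.linalg.LinAlgError as exc:
        raise ValueError("infeasible error correlation matrix") from exc
    rng = np.random.default_rng(seed)
    truth = rng.normal(size=n_samples)
    errors = rng.normal(size=(n_samples, n_models)) @ chol.T
    in_ad = rng.random((n_samples, n_models)) < covs
    rows = []
    for i in range(n_samples):
        for m in range(n_models):
            rows.append({
                "sample_id": f"s{i:05d}",
                "model_id": f"m{m}",
                "prediction": truth[i] + errors[i, m],
                "in_ad": bool(in_ad[i, m]),
            })
    return pd.DataFrame(rows), truth
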