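"""Fingerprints, structural keys and the integrated similarity index (SI).

Two families of structural descriptions feed the read-across machinery:

* binary fingerprints — an 881-bit substructure-key style fingerprint
  (PubChem family), a 1024-bit Daylight-style path fingerprint with ring
  features (Extended family) and a longer 2048-bit path fingerprint;
* three non-binary structural-key blocks — 35 constitutional counts (CD),
  11 heteroatom counts (HE) and 154 functional-group counts (FG).

Component similarities are combined into a single integrated similarity
index

    SI = S(FP)^0.4 * S(CD)^0.35 * S(HE)^0.1 * S(FG)^0.15

where S(FP) is the Maxwell-Pilliner index on the binary fingerprint and the
key-block similarities use the Bray-Curtis index.  SI ranges from 0 (no
similarity) to 1 (maximum similarity).  The weighted geometric product is
the default reading of the combination; a weighted arithmetic mean is
available and coincides with it whenever all components are equal (the
weights sum to 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, Fragments, Lipinski, rdMolDescriptors

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryFingerprint",
    "StructuralKeys",
    "SimilarityProfile",
    "IntegratedSimilarityWeights",
    "compute_fingerprint",
    "compute_structural_keys",
    "tanimoto",
    "maxwell_pilliner",
    "bray_curtis",
    "integrated_similarity",
    "similarity_profile",
    "compound_si",
    "adm_score",
]

_FP_LENGTHS = {"PUBCHEM": 881, "EXTENDED": 1024, "PATH": 2048}


@dataclass(frozen=True)
class BinaryFingerprint:
    """A fixed-length binary fingerprint of a given family."""

    kind: str
    bits: np.ndarray  # uint8 0/1 vector

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", arr)
        expected = _FP_LENGTHS.get(self.kind)
        if expected is not None and arr.size != expected:
            raise ValueError(f"{self.kind} fingerprint must have {expected} bits, got {arr.size}")

    @property
    def length(self) -> int:
        return int(self.bits.size)

    @classmethod
    def from_onbits(cls, kind: str, onbits, length: int | None = None) -> "BinaryFingerprint":
        length = length if length is not None else _FP_LENGTHS[kind]
        bits = np.zeros(length, dtype=np.uint8)
        bits[list(onbits)] = 1
        return cls(kind, bits)

    def to_hex(self) -> str:
        return np.packbits(self.bits).tobytes().hex()

    @classmethod
    def from_hex(cls, kind: str, hexstr: str, length: int | None = None) -> "BinaryFingerprint":
        length = length if length is not None else _FP_LENGTHS[kind]
        bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))[:length]
        return cls(kind, bits)


def compute_fingerprint(smiles_or_mol, kind: str = "EXTENDED") -> BinaryFingerprint:
    """Compute a binary fingerprint of the requested family for a molecule.

    PUBCHEM: RDKit pattern (substructure-key) fingerprint folded to 881 bits.
    EXTENDED: 1024-bit RDKit path fingerprint (Daylight notation with ring
    features).  PATH: the same family at 2048 bits.
    """
    mol = _as_mol(smiles_or_mol)
    kind = kind.upper()
    if kind == "PUBCHEM":
        bv = Chem.PatternFingerprint(mol, fpSize=881)
    elif kind == "EXTENDED":
        bv = Chem.RDKFingerprint(mol, fpSize=1024)
    elif kind == "PATH":
        bv = Chem.RDKFingerprint(mol, fpSize=2048)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    return BinaryFingerprint.from_onbits(kind, bv.GetOnBits())


def _as_mol(smiles_or_mol):
    if isinstance(smiles_or_mol, Chem.Mol):
        return smiles_or_mol
    mol = Chem.MolFromSmiles(smiles_or_mol)
    if mol is None:
        raise ValueError(f"unparseable SMILES {smiles_or_mol!r}")
    return mol


# --------------------------------------------------------------------------
# Structural-key blocks (35 constitutional + 11 heteroatom + 154 functional
# group counts).  The functional-group catalog is the RDKit fragment set
# (85 patterns) extended with 69 curated SMARTS, giving the 154 columns.
# --------------------------------------------------------------------------

_CD_NAMES = [
    "mw", "n_heavy", "n_bonds", "n_rot_bonds", "n_rings", "n_arom_rings",
    "n_aliph_rings", "n_sat_rings", "n_hbd", "n_hba", "n_C", "n_H",
    "n_hetero", "n_halogen", "n_sp3_C", "n_sp2_C", "n_sp_C", "n_arom_atoms",
    "n_arom_C", "n_arom_hetero", "n_ring_atoms", "n_single_bonds",
    "n_double_bonds", "n_triple_bonds", "n_arom_bonds", "n_charged",
    "n_pos_charge", "n_neg_charge", "n_stereo_centers", "frac_csp3",
    "n_amide_bonds", "n_bridgehead", "n_spiro", "n_radical", "n_frags",
]

_HE_SYMBOLS = ["N", "O", "S", "P", "F", "Cl", "Br", "I", "B", "Si"]
_HE_NAMES = [f"n_{s}" for s in _HE_SYMBOLS] + ["n_other_hetero"]

# 69 curated functional-group SMARTS complementing the RDKit catalog.
_EXTRA_FG_SMARTS: list[tuple[str, str]] = [
    ("methyl", "[CX4H3]"),
    ("methylene", "[CX4H2]"),
    ("methine", "[CX4H1]"),
    ("quaternary_C", "[CX4H0]"),
    ("alkene", "[CX3]=[CX3]"),
    ("alkyne", "[CX2]#[CX2]"),
    ("terminal_vinyl", "[CH2]=[CX3]"),
    ("carbonyl", "[CX3]=[OX1]"),
    ("thiocarbonyl", "[CX3]=[SX1]"),
    ("imine", "[CX3]=[NX2]"),
    ("enone", "[CX3]=[CX3][CX3]=[OX1]"),
    ("acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
    ("carbamate", "[NX3][CX3](=O)[OX2]"),
    ("urea_like", "[NX3][CX3](=O)[NX3]"),
    ("ether_acyclic", "[OX2;!R]([#6])[#6]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[#16X2]([#6])[#6]"),
    ("disulfide", "[SX2][SX2]"),
    ("peroxide", "[OX2][OX2]"),
    ("sulfonyl", "[SX4](=O)(=O)"),
    ("sulfonic_acid", "S(=O)(=O)[OX2H,OX1-]"),
    ("sulfonamide_any", "S(=O)(=O)[NX3]"),
    ("sulfoxide", "[SX3]=[OX1]"),
    ("nitroso", "[NX2]=[OX1]"),
    ("azo", "[NX2]=[NX2]"),
    ("azide", "N=[N+]=[N-]"),
    ("hydrazine_frag", "[NX3][NX3]"),
    ("hydroxylamine", "[NX3][OX2H]"),
    ("cyanamide", "[NX3][CX2]#[NX1]"),
    ("isocyanate", "[NX2]=C=[OX1]"),
    ("isothiocyanate", "[NX2]=C=[SX1]"),
    ("quaternary_N", "[NX4+]"),
    ("aromatic_NH", "[nH]"),
    ("pyridine_like_n", "[nX2]"),
    ("aromatic_O", "[o]"),
    ("aromatic_S", "[s]"),
    ("benzene_ring", "c1ccccc1"),
    ("fused_aromatic_atom", "[cR2]"),
    ("substituted_arom_C", "[cH0]"),
    ("unsubstituted_arom_C", "[cH]"),
    ("ring3_atom", "[r3]"),
    ("ring4_atom", "[r4]"),
    ("ring5_atom", "[r5]"),
    ("ring6_atom", "[r6]"),
    ("ring7_atom", "[r7]"),
    ("ring8_atom", "[r8]"),
    ("epoxide_O", "[OX2r3]"),
    ("aziridine_N", "[NX3r3]"),
    ("lactone", "[CX3](=O)[OX2][C;R]"),
    ("lactam", "[CX3](=O)[NX3][C;R]"),
    ("anhydride", "[CX3](=O)[OX2][CX3](=O)"),
    ("trifluoromethyl", "C(F)(F)F"),
    ("aliphatic_F", "[CX4][F]"),
    ("aliphatic_Cl", "[CX4][Cl]"),
    ("aliphatic_Br", "[CX4][Br]"),
    ("aliphatic_I", "[CX4][I]"),
    ("aryl_F", "[c][F]"),
    ("aryl_Cl", "[c][Cl]"),
    ("aryl_Br", "[c][Br]"),
    ("aryl_I", "[c][I]"),
    ("vinyl_halide", "[CX3]=[CX3][F,Cl,Br,I]"),
    ("gem_dihalide", "[CX4]([F,Cl,Br,I])[F,Cl,Br,I]"),
    ("P_oxide", "[PX4]=[OX1]"),
    ("P_sulfide", "[PX4]=[SX1]"),
    ("P_O_ester", "[PX4][OX2][#6]"),
    ("phosphorus_V", "[PX4]"),
    ("boronic", "[BX3]([OX2])[OX2]"),
    ("silane", "[Si]"),
    ("carboxylate_anion", "[CX3](=O)[OX1-]"),
]

_RDKIT_FR_NAMES = sorted(f for f in dir(Fragments) if f.startswith("fr_"))
_FG_NAMES = _RDKIT_FR_NAMES + [name for name, _ in _EXTRA_FG_SMARTS]
_EXTRA_FG_QUERIES = [(name, Chem.MolFromSmarts(sma)) for name, sma in _EXTRA_FG_SMARTS]
for _name, _q in _EXTRA_FG_QUERIES:
    if _q is None:  # pragma: no cover - catalog integrity
        raise RuntimeError(f"invalid SMARTS in functional-group catalog: {_name}")

CD_LENGTH, HE_LENGTH, FG_LENGTH = 35, 11, len(_FG_NAMES)


@dataclass(frozen=True)
class StructuralKeys:
    """The three non-binary key blocks: 35 CD, 11 HE and 154 FG counts."""

    cd: np.ndarray
    he: np.ndarray
    fg: np.ndarray

    def __post_init__(self) -> None:
        for attr, n in (("cd", CD_LENGTH), ("he", HE_LENGTH), ("fg", FG_LENGTH)):
            arr = np.asarray(getattr(self, attr), dtype=float)
            if arr.size != n:
                raise ValueError(f"{attr} block must have {n} entries, got {arr.size}")
            if (arr < 0).any():
                raise ValueError(f"{attr} block must be non-negative")
            object.__setattr__(self, attr, arr)


def compute_structural_keys(smiles_or_mol) -> StructuralKeys:
    """Populate the CD/HE/FG key blocks for one molecule."""
    mol = _as_mol(smiles_or_mol)
    ri = mol.GetRingInfo()
    atoms = list(mol.GetAtoms())
    bonds = list(mol.GetBonds())
    halogens = {9, 17, 35, 53}
    n_h = sum(a.GetTotalNumHs() for a in atoms)
    cd = [
        Descriptors.MolWt(mol),
        mol.GetNumHeavyAtoms(),
        mol.GetNumBonds(),
        rdMolDescriptors.CalcNumRotatableBonds(mol),
        rdMolDescriptors.CalcNumRings(mol),
        rdMolDescriptors.CalcNumAromaticRings(mol),
        rdMolDescriptors.CalcNumAliphaticRings(mol),
        rdMolDescriptors.CalcNumSaturatedRings(mol),
        Lipinski.NumHDonors(mol),
        Lipinski.NumHAcceptors(mol),
        sum(a.GetAtomicNum() == 6 for a in atoms),
        n_h,
        sum(a.GetAtomicNum() not in (1, 6) for a in atoms),
        sum(a.GetAtomicNum() in halogens for a in atoms),
        sum(a.GetAtomicNum() == 6 and str(a.GetHybridization()) == "SP3" for a in atoms),
        sum(a.GetAtomicNum() == 6 and str(a.GetHybridization()) == "SP2" for a in atoms),
        sum(a.GetAtomicNum() == 6 and str(a.GetHybridization()) == "SP" for a in atoms),
        sum(a.GetIsAromatic() for a in atoms),
        sum(a.GetIsAromatic() and a.GetAtomicNum() == 6 for a in atoms),
        sum(a.GetIsAromatic() and a.GetAtomicNum() != 6 for a in atoms),
        sum(ri.NumAtomRings(a.GetIdx()) > 0 for a in atoms),
        sum(b.GetBondType() == Chem.BondType.SINGLE for b in bonds),
        sum(b.GetBondType() == Chem.BondType.DOUBLE for b in bonds),
        sum(b.GetBondType() == Chem.BondType.TRIPLE for b in bonds),
        sum(b.GetIsAromatic() for b in bonds),
        sum(a.GetFormalCharge() != 0 for a in atoms),
        sum(a.GetFormalCharge() > 0 for a in atoms),
        sum(a.GetFormalCharge() < 0 for a in atoms),
        rdMolDescriptors.CalcNumAtomStereoCenters(mol),
        rdMolDescriptors.CalcFractionCSP3(mol),
        rdMolDescriptors.CalcNumAmideBonds(mol),
        rdMolDescriptors.CalcNumBridgeheadAtoms(mol),
        rdMolDescriptors.CalcNumSpiroAtoms(mol),
        sum(a.GetNumRadicalElectrons() for a in atoms),
        len(Chem.GetMolFrags(mol)),
    ]
    by_symbol = {s: 0 for s in _HE_SYMBOLS}
    other = 0
    for a in atoms:
        sym = a.GetSymbol()
        if sym in by_symbol:
            by_symbol[sym] += 1
        elif a.GetAtomicNum() not in (1, 6):
            other += 1
    he = [by_symbol[s] for s in _HE_SYMBOLS] + [other]
    fg = [float(getattr(Fragments, name)(mol)) for name in _RDKIT_FR_NAMES]
    fg += [float(len(mol.GetSubstructMatches(q))) for _, q in _EXTRA_FG_QUERIES]
    return StructuralKeys(cd=np.array(cd, float), he=np.array(he, float), fg=np.array(fg, float))


# --------------------------------------------------------------------------
# Similarity indices
# --------------------------------------------------------------------------

def _check_pair(a: BinaryFingerprint, b: BinaryFingerprint) -> None:
    if a.kind != b.kind or a.length != b.length:
        raise ValueError(f"fingerprint kind/length mismatch: {a.kind}/{a.length} vs {b.kind}/{b.length}")


def tanimoto(a: BinaryFingerprint, b: BinaryFingerprint) -> float:
    """Tanimoto (Jaccard) similarity |a & b| / |a | b|.

    Two all-zero fingerprints are identical objects and score 1.0 (logged).
    """
    _check_pair(a, b)
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        logger.info("tanimoto of two empty fingerprints defined as 1.0")
        return 1.0
    return inter / union


def maxwell_pilliner(a: BinaryFingerprint, b: BinaryFingerprint) -> float:
    """Maxwell-Pilliner association index, clamped to [0, 1].

    With on/on (p), on/off (q), off/on (r) and off/off (s) bit counts the raw
    index is ``2(ps - qr) / ((p+q)(q+s) + (p+r)(r+s))``.  The raw range
    includes negatives for anti-correlated pairs; since SI components live in
    [0, 1], negative values are clamped to 0.
    """
    _check_pair(a, b)
    p = int(np.count_nonzero(a.bits & b.bits))
    q = int(np.count_nonzero(a.bits & ~b.bits & 1))
    r = int(np.count_nonzero(~a.bits & 1 & b.bits))
    s = a.length - p - q - r
    denom = (p + q) * (q + s) + (p + r) * (r + s)
    if denom == 0:
        raise ValueError("degenerate fingerprint pair: Maxwell-Pilliner denominator is zero")
    raw = 2.0 * (p * s - q * r) / denom
    return min(1.0, max(0.0, raw))


def bray_curtis(x, y) -> float:
    """Bray-Curtis similarity 1 - sum|x-y| / sum(x+y) on count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("count vectors must have equal length")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("count vectors must be non-negative")
    total = float(np.sum(x + y))
    if total == 0:
        logger.warning("Bray-Curtis of two all-zero vectors defined as 1.0")
        return 1.0
    return 1.0 - float(np.sum(np.abs(x - y))) / total


@dataclass(frozen=True)
class SimilarityProfile:
    """Component similarities feeding the integrated index."""

    s_fp: float
    s_cd: float
    s_he: float
    s_fg: float

    def __post_init__(self) -> None:
        for name in ("s_fp", "s_cd", "s_he", "s_fg"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class IntegratedSimilarityWeights:
    """SI component weights; they must be non-negative and sum to 1."""

    w_fp: float = 0.4
    w_cd: float = 0.35
    w_he: float = 0.1
    w_fg: float = 0.15
    mode: str = "geometric"

    def __post_init__(self) -> None:
        w = (self.w_fp, self.w_cd, self.w_he, self.w_fg)
        if any(x < 0 for x in w) or not math.isclose(sum(w), 1.0, abs_tol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1")
        if self.mode not in ("geometric", "arithmetic"):
            raise ValueError("mode must be 'geometric' or 'arithmetic'")


def integrated_similarity(
    p: SimilarityProfile, w: IntegratedSimilarityWeights = IntegratedSimilarityWeights()
) -> float:
    """Combine component similarities into the integrated similarity index SI."""
    comps = (p.s_fp, p.s_cd, p.s_he, p.s_fg)
    weights = (w.w_fp, w.w_cd, w.w_he, w.w_fg)
    if w.mode == "arithmetic":
        return float(sum(wi * ci for wi, ci in zip(weights, comps)))
    out = 1.0
    for wi, ci in zip(weights, comps):
        if ci == 0.0 and wi > 0:
            return 0.0
        out *= ci ** wi
    return float(min(1.0, max(0.0, out)))


def similarity_profile(
    fp_a: BinaryFingerprint, keys_a: StructuralKeys,
    fp_b: BinaryFingerprint, keys_b: StructuralKeys,
) -> SimilarityProfile:
    """Component similarities for one compound pair (MP on FP, Bray-Curtis on keys)."""
    return SimilarityProfile(
        s_fp=maxwell_pilliner(fp_a, fp_b),
        s_cd=bray_curtis(keys_a.cd, keys_b.cd),
        s_he=bray_curtis(keys_a.he, keys_b.he),
        s_fg=bray_curtis(keys_a.fg, keys_b.fg),
    )


def compound_si(
    smiles_a: str, smiles_b: str,
    weights: IntegratedSimilarityWeights = IntegratedSimilarityWeights(),
    fp_kind: str = "EXTENDED",
) -> float:
    """Integrated similarity between two SMILES (convenience wrapper)."""
    prof = similarity_profile(
        compute_fingerprint(smiles_a, fp_kind), compute_structural_keys(smiles_a),
        compute_fingerprint(smiles_b, fp_kind), compute_structural_keys(smiles_b),
    )
    return integrated_similarity(prof, weights)


#: ADM tier thresholds: (pubchem, extended) minima for scores 2..5.  Only the
#: score-2 anchor (0.60/0.30, the in-AD boundary) is fixed by the method; the
#: upper tiers are a monotone interpolation and may be reconfigured.
DEFAULT_ADM_TIERS: tuple[tuple[float, float], ...] = (
    (0.60, 0.30), (0.70, 0.45), (0.80, 0.60), (0.90, 0.75),
)


def adm_score(
    mean_pubchem_sim: float, mean_extended_sim: float,
    tiers: tuple[tuple[float, float], ...] = DEFAULT_ADM_TIERS,
) -> int:
    """Applicability-domain measure for the local-model engine, 1 (out) to 5 (in).

    The score is 1 plus the number of tiers passed; a tier is passed when both
    mean similarities reach its thresholds.  Score >= 2 (in AD) iff the mean
    PubChem similarity >= 0.60 and the mean Extended similarity >= 0.30.
    """
    if not (0 <= mean_pubchem_sim <= 1 and 0 <= mean_extended_sim <= 1):
        raise ValueError("mean similarities must lie in [0, 1]")
    score = 1
    for t_pub, t_ext in tiers:
        if mean_pubchem_sim >= t_pub and mean_extended_sim >= t_ext:
            score += 1
        else:
            break
    return score
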