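"""Compound-side features: folded circular fingerprints + physicochemical block.

Ligands are described by a Morgan-style circular substructure fingerprint
(diameter 6, i.e. radius 3) hashed and folded to 512 bits, optionally
followed by an ordered block of physicochemical properties (logP, an
estimated log solubility, atom/bond counts, H-bond donors and acceptors,
size terms, ring and chain counts).  Diverse compound sets benefit from the
physicochemical block; congeneric series usually do not, so it is off by
default and enabled per dataset.

Structures are accepted as SMILES; parsing and property calculation are
delegated to RDKit, with molecules canonicalized by graph so equivalent
SMILES spellings give identical features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "LigandFeatureSpec",
    "circular_fingerprint",
    "physchem_block",
    "ligand_feature_vector",
    "LigandFeaturizer",
    "DEFAULT_PHYSCHEM_PROPERTIES",
]

_POS_IONIZABLE = Chem.MolFromSmarts("[+,$([NX3;H2,H1,H0;!$(NC=O);!$(N=*)]),$(n1ccncc1)]")
_NEG_IONIZABLE = Chem.MolFromSmarts("[-,$([CX3](=O)[OX2H1]),$([SX4](=O)(=O)[OX2H1]),$(c1ccccc1[OX2H1])]")


def _esol_log_solubility(mol) -> float:
    """Delaney ESOL estimate of aqueous log solubility (log mol/L)."""
    logp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rb = Lipinski.NumRotatableBonds(mol)
    heavy = mol.GetNumHeavyAtoms()
    ap = (sum(1 for a in mol.GetAtoms() if a.GetIsAromatic()) / heavy
          if heavy else 0.0)
    return 0.16 - 0.63 * logp - 0.0062 * mw + 0.066 * rb - 0.74 * ap


def _n_matches(mol, pattern) -> int:
    return len(mol.GetSubstructMatches(pattern))


PROPERTY_FUNCS = {
    "logp": Crippen.MolLogP,
    "log_solubility": _esol_log_solubility,
    "n_atoms": lambda m: m.GetNumHeavyAtoms(),
    "n_pos_ionizable": lambda m: _n_matches(m, _POS_IONIZABLE),
    "n_neg_ionizable": lambda m: _n_matches(m, _NEG_IONIZABLE),
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "molar_refractivity": Crippen.MolMR,  # volume proxy
    "mol_weight": Descriptors.MolWt,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "n_bonds": lambda m: m.GetNumBonds(),
    "n_aromatic_bonds": lambda m: sum(1 for b in m.GetBonds() if b.GetIsAromatic()),
    "n_rotatable_bonds": Lipinski.NumRotatableBonds,
    "ring_count": rdMolDescriptors.CalcNumRings,
    "n_chain_atoms": lambda m: sum(1 for a in m.GetAtoms() if not a.IsInRing()),
}

DEFAULT_PHYSCHEM_PROPERTIES = tuple(PROPERTY_FUNCS)


@dataclass(frozen=True)
class LigandFeatureSpec:
    """Fingerprint geometry plus the optional physicochemical block."""

    fingerprint_bits: int = 512
    fingerprint_diameter: int = 6
    include_physchem: bool = False
    physchem_property_list: tuple = DEFAULT_PHYSCHEM_PROPERTIES

    def __post_init__(self):
        bits = self.fingerprint_bits
        if bits < 1 or bits & (bits - 1):
            raise ValueError("fingerprint_bits must be a power of two")
        if self.fingerprint_diameter < 0 or self.fingerprint_diameter % 2:
            raise ValueError("fingerprint_diameter must be even and >= 0")
        unknown = set(self.physchem_property_list) - set(PROPERTY_FUNCS)
        if unknown:
            raise ValueError(f"unknown physchem properties {sorted(unknown)}")
        object.__setattr__(self, "physchem_property_list",
                           tuple(self.physchem_property_list))

    @property
    def width(self) -> int:
        return self.fingerprint_bits + (
            len(self.physchem_property_list) if self.include_physchem else 0)


def _parse(structure: str):
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable structure: {structure!r}")
    return mol


def circular_fingerprint(structure: str, spec: LigandFeatureSpec | None = None) -> np.ndarray:
    """Folded circular fingerprint as a 0/1 vector of ``fingerprint_bits``."""
    spec = spec or LigandFeatureSpec()
    mol = _parse(structure)
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=spec.fingerprint_diameter // 2, fpSize=spec.fingerprint_bits)
    fp = gen.GetFingerprint(mol)
    return np.array(fp, dtype=float)


def physchem_block(structure: str, spec: LigandFeatureSpec | None = None) -> np.ndarray:
    """Ordered vector of the named physicochemical properties."""
    spec = spec or LigandFeatureSpec(include_physchem=True)
    mol = _parse(structure)
    return np.array([PROPERTY_FUNCS[name](mol)
                     for name in spec.physchem_property_list], dtype=float)


def ligand_feature_vector(structure: str, spec: LigandFeatureSpec | None = None) -> np.ndarray:
    """Fingerprint block, then the physchem block iff ``include_physchem``."""
    spec = spec or LigandFeatureSpec()
    fp = circular_fingerprint(structure, spec)
    if spec.include_physchem:
        return np.concatenate([fp, physchem_block(structure, spec)])
    return fp


def ligand_feature_names(spec: LigandFeatureSpec) -> tuple:
    names = tuple(f"fp{b}" for b in range(spec.fingerprint_bits))
    if spec.include_physchem:
        names += tuple(spec.physchem_property_list)
    return names


class LigandFeaturizer(TransformerMixin, BaseEstimator):
    """scikit-learn transformer from SMILES lists to feature matrices."""

    def __init__(self, spec=None):
        self.spec = spec

    def _spec(self) -> LigandFeatureSpec:
        return self.spec or LigandFeatureSpec()

    def fit(self, X, y=None):
        self.feature_names_ = ligand_feature_names(self._spec())
        self.n_features_out_ = len(self.feature_names_)
        return self

    def transform(self, X) -> np.ndarray:
        spec = self._spec()
        return np.vstack([ligand_feature_vector(s, spec) for s in X])

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.feature_names_, dtype=object)
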