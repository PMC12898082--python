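"""SMILES → attributed molecular graph featurization.

Molecules are represented as hydrogen-suppressed graphs: hydrogens never
appear as nodes, but each heavy atom carries its attached-hydrogen count as
a one-hot feature block.  Atom and bond properties are one-hot encoded with
a fixed block layout so every node vector has width 94 and every directed
edge vector width 10.  Out-of-vocabulary categories clamp to a designated
last slot, so each one-hot block always sums to exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem.Descriptors import ExactMolWt

RDLogger.DisableLog("rdApp.*")
logger = logging.getLogger(__name__)

# 60 elements seen across organic / organometallic EI-MS libraries, plus one
# fallback slot for anything else (width 61).  The list is configuration, not
# chemistry: widths must stay fixed for the network input layer.
DEFAULT_ATOMIC_NUMBERS: tuple[int, ...] = (
    3, 4, 5, 6, 7, 8, 9,
    11, 12, 13, 14, 15, 16, 17,
    19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35,
    37, 38, 39, 40, 41, 42, 43, 44, 45, 46, 47, 48, 49, 50, 51, 52, 53,
    55, 56, 57, 73, 74, 75, 78, 79, 80, 81, 82, 83,
)

_HYBRIDIZATIONS = (
    Chem.HybridizationType.S,
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
)  # + fallback slot (SP3D2, unspecified, ...) -> 6 categories

_BOND_TYPES = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

_BOND_STEREO = (
    Chem.BondStereo.STEREONONE,
    Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOE,
)  # + fallback slot -> 4 stereo configurations


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class FeatureSchema:
    """Block layout of the one-hot atom/bond feature vectors.

    The last slot of each categorical block is the out-of-vocabulary
    fallback; the radical-electron block is a single raw count.
    """

    atomic_number_slots: tuple[int, ...] = DEFAULT_ATOMIC_NUMBERS
    degree_width: int = 7            # degrees 0..6, overflow clamps to 6
    valence_width: int = 7           # explicit valence 0..6
    formal_charge_slots: tuple[int, ...] = (-2, -1, 0, 1, 2)
    radical_electrons_width: int = 1
    hybridization_width: int = 6
    aromatic_width: int = 1
    hydrogen_count_width: int = 6    # 0..5 attached hydrogens
    bond_type_width: int = 4
    conjugation_width: int = 1
    in_ring_width: int = 1
    chirality_width: int = 4

    def __post_init__(self):
        if len(set(self.atomic_number_slots)) != len(self.atomic_number_slots):
            raise ValueError("atomic_number_slots contains duplicates")
        if len(set(self.formal_charge_slots)) != len(self.formal_charge_slots):
            raise ValueError("formal_charge_slots contains duplicates")

    @property
    def atom_width(self) -> int:
        return (len(self.atomic_number_slots) + 1 + self.degree_width
                + self.valence_width + len(self.formal_charge_slots)
                + self.radical_electrons_width + self.hybridization_width
                + self.aromatic_width + self.hydrogen_count_width)

    @property
    def bond_width(self) -> int:
        return (self.bond_type_width + self.conjugation_width
                + self.in_ring_width + self.chirality_width)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("atomic_number_slots", "formal_charge_slots"):
            if key in raw:
                raw[key] = tuple(int(v) for v in raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        payload = {
            "atomic_number_slots": list(self.atomic_number_slots),
            "degree_width": self.degree_width,
            "valence_width": self.valence_width,
            "formal_charge_slots": list(self.formal_charge_slots),
            "radical_electrons_width": self.radical_electrons_width,
            "hybridization_width": self.hybridization_width,
            "aromatic_width": self.aromatic_width,
            "hydrogen_count_width": self.hydrogen_count_width,
            "bond_type_width": self.bond_type_width,
            "conjugation_width": self.conjugation_width,
            "in_ring_width": self.in_ring_width,
            "chirality_width": self.chirality_width,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)


DEFAULT_SCHEMA = FeatureSchema()


@dataclass
class MoleculeGraph:
    """Hydrogen-suppressed attributed graph of one molecule.

    Every undirected bond is stored as two directed edges with identical
    features; ``mono_mass`` is the monoisotopic mass of the neutral molecule
    including its (suppressed) hydrogens.
    """

    node_features: np.ndarray        # (n_atoms, atom_width)
    edge_index: np.ndarray           # (n_directed_edges, 2) int
    edge_features: np.ndarray        # (n_directed_edges, bond_width)
    mono_mass: float
    structure_key: str
    schema: FeatureSchema = field(default=DEFAULT_SCHEMA, repr=False)

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[0]


def _clamped_one_hot(value: int, width: int) -> np.ndarray:
    vec = np.zeros(width)
    vec[min(max(int(value), 0), width - 1)] = 1.0
    return vec


def _slot_one_hot(value, slots: tuple) -> np.ndarray:
    vec = np.zeros(len(slots) + 1)
    try:
        vec[slots.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _exact_slot_one_hot(value, slots: tuple) -> np.ndarray:
    """One-hot over exactly ``len(slots)`` slots; out-of-vocabulary values
    clamp to the last slot (no extra fallback column)."""
    vec = np.zeros(len(slots))
    try:
        vec[slots.index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def _atom_features(atom: Chem.Atom, schema: FeatureSchema) -> np.ndarray:
    hyb_slots = _HYBRIDIZATIONS[: schema.hybridization_width - 1]
    return np.concatenate([
        _slot_one_hot(atom.GetAtomicNum(), schema.atomic_number_slots),
        _clamped_one_hot(atom.GetDegree(), schema.degree_width),
        _clamped_one_hot(atom.GetExplicitValence(), schema.valence_width),
        _exact_slot_one_hot(atom.GetFormalCharge(), schema.formal_charge_slots),
        np.array([float(atom.GetNumRadicalElectrons())]),
        _slot_one_hot(atom.GetHybridization(), hyb_slots),
        np.array([float(atom.GetIsAromatic())]),
        _clamped_one_hot(atom.GetTotalNumHs(), schema.hydrogen_count_width),
    ])


def _bond_features(bond: Chem.Bond, schema: FeatureSchema) -> np.ndarray:
    return np.concatenate([
        _slot_one_hot(bond.GetBondType(), _BOND_TYPES[: schema.bond_type_width - 1]),
        np.array([float(bond.GetIsConjugated())]),
        np.array([float(bond.IsInRing())]),
        _slot_one_hot(bond.GetStereo(), _BOND_STEREO[: schema.chirality_width - 1]),
    ])


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    if mol.GetNumHeavyAtoms() == 0:
        raise SmilesParseError(f"molecule has no heavy atoms: {smiles!r}")
    return mol


def canonical_key(smiles: str) -> str:
    """Canonical isomeric SMILES; identical for any rendering of a molecule."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def featurize(smiles: str, schema: FeatureSchema = DEFAULT_SCHEMA) -> MoleculeGraph:
    """Convert one isomeric SMILES to an attributed, hydrogen-suppressed graph."""
    mol = mol_from_smiles(smiles)
    node_features = np.array(
        [_atom_features(a, schema) for a in mol.GetAtoms()]
    ).reshape(mol.GetNumAtoms(), schema.atom_width)

    edges: list[tuple[int, int]] = []
    feats: list[np.ndarray] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        f = _bond_features(bond, schema)
        edges.extend([(i, j), (j, i)])
        feats.extend([f, f])
    edge_index = (np.array(edges, dtype=np.intp) if edges
                  else np.zeros((0, 2), dtype=np.intp))
    edge_features = (np.array(feats) if feats
                     else np.zeros((0, schema.bond_width)))

    return MoleculeGraph(
        node_features=node_features,
        edge_index=edge_index,
        edge_features=edge_features,
        mono_mass=float(ExactMolWt(mol)),
        structure_key=Chem.MolToSmiles(mol),
        schema=schema,
    )


def canonical_dedup(smiles_list) -> list[str]:
    """Keep the first occurrence of each structure (by canonical SMILES).

    Order-preserving; unparsable entries are dropped with one summary
    warning rather than raising.
    """
    seen: set[str] = set()
    kept: list[str] = []
    n_invalid = 0
    for smi in smiles_list:
        try:
            key = canonical_key(smi)
        except SmilesParseError:
            n_invalid += 1
            continue
        if key not in seen:
            seen.add(key)
            kept.append(smi)
    if n_invalid:
        logger.warning("canonical_dedup dropped %d invalid SMILES", n_invalid)
    return kept


def read_smiles_file(path) -> list[str]:
    """Read a plain-text SMILES list (one per line, optional tab-separated id)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            out.append(line.split("\t")[0].split()[0])
    return out
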